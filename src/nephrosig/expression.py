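"""Expression-matrix and sample-annotation I/O.

Expression data are log2-normalized intensities, genes (or probes) in rows
and samples in columns, read from TSV. Sample annotations carry the cohort,
microdissected compartment (glomerular / tubulointerstitial / whole), group
(lupus nephritis, living donor, or another kidney disease), optional
histological class and treatment flag, and clinical covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "read_expression",
    "read_sample_table",
    "read_probe_map",
    "collapse_probes",
    "ensure_log2",
    "COMPARTMENTS",
]

COMPARTMENTS = ("glomerular", "tubulointerstitial", "whole")

COVARIATE_COLUMNS = ("eGFR", "SCr", "BUN", "SLEDAI", "C3", "C4", "HNE_score")


@dataclass
class ExpressionMatrix:
    """log2 expression values, genes x samples.

    Wraps a DataFrame with unique gene index and unique sample columns;
    values must be finite and there must be at least two samples.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[1] < 2:
            raise ValueError(f"expression matrix needs >=2 samples, got {df.shape[1]}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate gene rows: {dups}")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample columns")
        if not np.isfinite(df.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class SampleTable:
    """Per-sample annotations indexed by sample id."""

    table: pd.DataFrame

    REQUIRED = ("cohort", "compartment", "group")

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids in sample table")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"sample table missing required column {col!r}")
        bad = set(df["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment labels: {sorted(bad)}")
        if "eGFR" in df.columns:
            egfr = df["eGFR"].dropna()
            if (egfr < 0).any():
                raise ValueError("eGFR must be >= 0")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def covariate(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"covariate {name!r} not in sample table")
        return self.table[name]

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        missing = matrix.samples.difference(self.sample_ids)
        if len(missing):
            raise ValueError(f"matrix samples absent from sample table: {list(missing)[:5]}")

    def subset(self, sample_ids) -> "SampleTable":
        return SampleTable(self.table.loc[list(sample_ids)])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="sample_id")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, index_col="sample_id")
    return SampleTable(df)


def read_expression(path: str | Path, sample_table: SampleTable) -> ExpressionMatrix:
    """Read a genes-x-samples TSV and align columns to the sample table.

    Every matrix column must appear in the sample table (extra table rows
    are allowed); the returned column order follows the sample table.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty expression file")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            loc = bad.index[0] if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value in column {col!r} at gene {loc!r}")
    unknown = [s for s in df.columns if s not in sample_table.sample_ids]
    if unknown:
        raise ValueError(f"{path}: sample(s) {unknown[:5]} not in sample table")
    order = [s for s in sample_table.sample_ids if s in df.columns]
    return ExpressionMatrix(df.loc[:, order])


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probe->gene TSV (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"], dtype=str)
    if df["probe"].duplicated().any():
        dup = df["probe"][df["probe"].duplicated()].iloc[0]
        raise ValueError(f"{path}: probe {dup!r} maps to multiple genes")
    return dict(zip(df["probe"], df["gene"].str.strip().str.upper()))


def collapse_probes(
    matrix: ExpressionMatrix,
    probe_map: Mapping[str, str],
    method: str = "max_mean",
) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene symbol.

    ``max_mean`` (default) keeps, for each gene, the probe with the highest
    mean expression across samples; ``mean`` averages all probes of a gene.
    Unmapped probes are dropped (count reported via warning).
    """
    if method not in ("max_mean", "mean"):
        raise ValueError(f"unknown collapse method {method!r}")
    df = matrix.values
    mapped = df.index.map(lambda p: probe_map.get(p))
    keep = mapped.notna()
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no probes mapped to genes; empty result")
    if n_dropped:
        warnings.warn(f"collapse_probes: dropped {n_dropped} unmapped probe(s)", stacklevel=2)
    sub = df.loc[keep].copy()
    genes = pd.Index(mapped[keep], name="gene")
    if method == "mean":
        out = sub.groupby(genes).mean()
    else:
        means = sub.mean(axis=1).to_numpy()
        order = np.lexsort((-means, genes.to_numpy()))
        sub = sub.iloc[order]
        first = ~pd.Index(genes.to_numpy()[order]).duplicated()
        out = sub.loc[first]
        out.index = pd.Index(genes.to_numpy()[order][first], name="gene")
        out = out.sort_index()
    return ExpressionMatrix(out)


def ensure_log2(
    matrix: ExpressionMatrix, threshold: float = 50.0
) -> tuple[ExpressionMatrix, bool]:
    """Heuristically log2-transform a matrix that looks like linear scale.

    Normalized microarray log2 values rarely exceed ~16; a maximum above
    ``threshold`` triggers x -> log2(x+1). Negative values together with a
    large maximum are ambiguous and raise.
    """
    vals = matrix.values.to_numpy()
    if vals.max() <= threshold:
        return matrix, False
    if vals.min() < 0:
        raise ValueError(
            "ambiguous scale: maximum suggests linear intensities but negative values present"
        )
    return ExpressionMatrix(np.log2(matrix.values + 1.0)), True
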