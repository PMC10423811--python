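"""Composite gene-expression signature scores.

The pathway-activity statistic is the per-sample average of z-scored log2
expression over a gene set. z-scoring is per gene across all samples of a
stratum (cohort x compartment, cases and controls together — the group
contrast needs a common reference), with the sample standard deviation
(n−1 denominator). Genes with zero variance are excluded; genes absent
from the matrix reduce a set's coverage rather than contributing zeros.

Two exact consequences used as correctness checks downstream: every set's
scores sum to zero across the stratum's samples, and scores are invariant
to per-gene affine rescaling of the input expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleTable
from .genesets import GeneSet, Registry

__all__ = ["ScoreTable", "CompositeScore", "zscore_genes", "composite_score", "score_all"]


def zscore_genes(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """z-score each gene row: (x − mean) / sd, sample sd (ddof=1).

    Returns the z-matrix and the list of excluded constant genes
    (sd == 0). Requires at least two samples.
    """
    df = matrix.values
    if df.shape[1] < 2:
        raise ValueError("z-scoring needs >=2 samples")
    sd = df.std(axis=1, ddof=1)
    # rows whose spread is at float-rounding level carry no signal: treat as constant
    tol = 1e-12 * np.maximum(1.0, df.abs().max(axis=1))
    constant = sd <= tol
    excluded = df.index[constant].tolist()
    kept = df.loc[~constant]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd.loc[~constant], axis=0)
    return z, excluded


@dataclass(frozen=True)
class CompositeScore:
    """Per-sample composite score for one gene set."""

    set_name: str
    scores: pd.Series
    coverage: float  # fraction of set genes present (and non-constant)
    n_present: int
    usable: bool


def composite_score(
    zmatrix: pd.DataFrame, geneset: GeneSet, min_coverage: float = 0.5
) -> CompositeScore:
    """Unweighted mean of z-values over the set genes present in the z-matrix.

    ``coverage`` = (#present)/(set size); below ``min_coverage`` the score
    is still returned but flagged unusable. A set with zero genes present
    raises.
    """
    present = [g for g in geneset.genes if g in zmatrix.index]
    if not present:
        raise ValueError(f"gene set {geneset.name!r}: no genes present in matrix")
    coverage = len(present) / len(geneset)
    scores = zmatrix.loc[present].mean(axis=0)
    scores.name = geneset.name
    return CompositeScore(
        set_name=geneset.name,
        scores=scores,
        coverage=coverage,
        n_present=len(present),
        usable=coverage >= min_coverage,
    )


@dataclass
class ScoreTable:
    """Sets (rows) x samples (columns) of composite scores for one stratum."""

    scores: pd.DataFrame
    coverage: dict[str, float]
    usable: dict[str, bool]
    excluded_genes: list[str]
    stratum: tuple

    def to_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="set")

    def sidecar(self) -> dict:
        return {
            "stratum": list(self.stratum),
            "coverage": self.coverage,
            "usable": self.usable,
            "n_excluded_constant_genes": len(self.excluded_genes),
        }


def score_all(
    matrix: ExpressionMatrix,
    sample_table: SampleTable,
    registry: Registry | Iterable[GeneSet],
    stratify_by: Sequence[str] = ("cohort", "compartment"),
    min_coverage: float = 0.5,
) -> dict[tuple, ScoreTable]:
    """Score every registry set within each stratum of the sample table.

    z-scoring and composite scoring run independently within each stratum
    (over all its samples, cases and controls together). Strata with fewer
    than two samples are skipped with a warning.
    """
    sample_table.check_covers(matrix)
    meta = sample_table.table.loc[matrix.samples]
    genesets = list(registry)
    out: dict[tuple, ScoreTable] = {}
    for key, sub in meta.groupby(list(stratify_by), sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        ids = sub.index.tolist()
        if len(ids) < 2:
            warnings.warn(f"stratum {key}: <2 samples, skipped", stacklevel=2)
            continue
        z, excluded = zscore_genes(matrix.subset_samples(ids))
        rows, coverage, usable = {}, {}, {}
        for gs in genesets:
            cs = composite_score(z, gs, min_coverage=min_coverage)
            rows[gs.name] = cs.scores
            coverage[gs.name] = cs.coverage
            usable[gs.name] = cs.usable
        out[key] = ScoreTable(
            scores=pd.DataFrame(rows).T,
            coverage=coverage,
            usable=usable,
            excluded_genes=excluded,
            stratum=key,
        )
    return out
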