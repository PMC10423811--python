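"""End-to-end orchestration: sets -> scores -> comparisons -> DE -> candidates.

The pipeline reproduces the analysis shape of the compartment-stratified
renal transcriptome study: build the 15-set registry, score every set in
every cohort x compartment stratum, compare LN against LD (and optional
clinical strata), run moderated-t differential expression per stratum,
intersect direction-consistent DEGs across cohorts with the metabolic
union, and correlate pathway scores with each other and with clinical
covariates. Outputs are plain TSV/JSON; the run report carries a config
hash and per-file checksums for provenance.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import time
import warnings
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .compare import spearman_correlate, stratified_compare
from .diffexpr import fit_moderated_t, screen_degs
from .expression import (
    ExpressionMatrix,
    collapse_probes,
    ensure_log2,
    read_expression,
    read_probe_map,
    read_sample_table,
)
from .genesets import build_registry, default_registry, load_recipes, read_gmt, validate_registry
from .intersect import intersect_degs
from .scoring import score_all
from .simulate import PathwayEffect, SimConfig, simulate_cohort

__all__ = ["PipelineConfig", "ExpressionInput", "run_pipeline", "RunReport"]


class ExpressionInput(BaseModel):
    cohort: str
    compartment: str
    path: str


class Thresholds(BaseModel):
    lfc: float = 1.0
    alpha: float = 0.05
    min_coverage: float = 0.5

    @field_validator("lfc", "alpha", "min_coverage")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("thresholds must be positive")
        return v


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable)."""

    outdir: str
    seed: int = 0
    # gene sets: defaults to the bundled fixture registry
    gmt: Optional[str] = None
    recipes: Optional[str] = None
    # real data (if omitted, a synthetic cohort is simulated)
    expression: list[ExpressionInput] = Field(default_factory=list)
    sample_table: Optional[str] = None
    probe_map: Optional[str] = None
    # synthetic-data knobs
    n_genes: int = 4000
    sim_pathway_effects: Optional[list[dict]] = None  # [{set_name, compartment, delta}]
    thresholds: Thresholds = Field(default_factory=Thresholds)
    groupings: list[str] = Field(default_factory=lambda: ["ln_vs_ld"])
    correlate_covariates: list[str] = Field(
        default_factory=lambda: ["eGFR", "SCr", "BUN", "SLEDAI", "C3", "C4", "HNE_score"]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class RunReport(dict):
    """JSON-serializable run summary (stages, warnings, file checksums)."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_registry(config: PipelineConfig):
    if config.gmt and config.recipes:
        return build_registry(read_gmt(config.gmt), load_recipes(config.recipes))
    if config.gmt or config.recipes:
        raise ValueError("gmt and recipes must be given together")
    return default_registry()


def _load_data(config: PipelineConfig, registry):
    if not config.expression:
        kwargs = {}
        if config.sim_pathway_effects is not None:
            kwargs["pathway_effects"] = tuple(
                PathwayEffect(**e) for e in config.sim_pathway_effects
            )
        sim = simulate_cohort(
            SimConfig(seed=config.seed, n_genes=config.n_genes, **kwargs), registry
        )
        return sim.matrices, sim.sample_table, sim.truth
    if config.sample_table is None:
        raise ValueError("sample_table is required when expression paths are given")
    table = read_sample_table(config.sample_table)
    probe_map = read_probe_map(config.probe_map) if config.probe_map else None
    matrices = {}
    for entry in config.expression:
        m = read_expression(entry.path, table)
        m, _ = ensure_log2(m)
        if probe_map:
            m = collapse_probes(m, probe_map)
        matrices[(entry.cohort, entry.compartment)] = m
    return matrices, table, None


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; write outputs atomically to ``config.outdir``.

    Any stage failure aborts with a stage-named error and leaves no
    partial output directory behind.
    """
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()):
        raise FileExistsError(f"output directory {outdir} exists and is not empty")
    tmpdir = outdir.parent / f".{outdir.name}.tmp"
    if tmpdir.exists():
        shutil.rmtree(tmpdir)
    tmpdir.mkdir(parents=True)

    report = RunReport(
        config=config.model_dump(),
        config_hash=config.config_hash(),
        version=__version__,
        stages=[],
        warnings=[],
    )
    t_start = time.time()
    stage = "init"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            stage = "build-sets"
            registry = _load_registry(config)
            validation = validate_registry(registry)
            pd.DataFrame(list(validation.rows)).to_csv(
                tmpdir / "registry_validation.tsv", sep="\t", index=False
            )
            report["registry"] = {
                "n_sets": validation.n_total,
                "n_size_match": validation.n_match,
                "overall_pass": validation.overall_pass,
            }

            stage = "load-data"
            matrices, table, truth = _load_data(config, registry)
            table.to_csv(tmpdir / "sample_table.csv")
            if truth is not None:
                truth.to_json(tmpdir / "sim_truth.json")
            for (cohort, comp), m in matrices.items():
                m.to_tsv(tmpdir / f"expression_{cohort}_{comp}.tsv")

            stage = "score"
            score_tables = {}
            for (cohort, comp), m in matrices.items():
                st = score_all(
                    m, table, registry, min_coverage=config.thresholds.min_coverage
                )
                score_tables.update(st)
            sidecar = {}
            for stratum, st in score_tables.items():
                name = "_".join(stratum)
                st.to_tsv(tmpdir / f"scores_{name}.tsv")
                sidecar[name] = st.sidecar()
            (tmpdir / "scores_coverage.json").write_text(json.dumps(sidecar, indent=2))

            stage = "compare"
            comparisons = stratified_compare(score_tables, table, config.groupings)
            pd.DataFrame([c.as_dict() for c in comparisons]).to_csv(
                tmpdir / "comparisons.tsv", sep="\t", index=False
            )
            report["n_comparisons"] = len(comparisons)

            stage = "correlate"
            corr_rows = []
            metabolic = [gs.name for gs in registry.by_category("metabolic")]
            for stratum, st in score_tables.items():
                if "ferroptosis" not in st.scores.index:
                    continue
                ferro = st.scores.loc["ferroptosis"]
                for name in metabolic:
                    r = spearman_correlate(
                        ferro, st.scores.loc[name], var_x="ferroptosis", var_y=name
                    )
                    corr_rows.append({"stratum": "/".join(stratum), **r.as_dict()})
                meta = table.table.loc[st.scores.columns]
                for cov in config.correlate_covariates:
                    if cov not in meta.columns:
                        continue
                    y = pd.to_numeric(meta[cov], errors="coerce")
                    if y.notna().sum() < 3 or y.dropna().nunique() < 2:
                        continue
                    r = spearman_correlate(
                        ferro.to_numpy(), y.to_numpy(), var_x="ferroptosis", var_y=cov
                    )
                    corr_rows.append({"stratum": "/".join(stratum), **r.as_dict()})
            pd.DataFrame(corr_rows).to_csv(tmpdir / "correlations.tsv", sep="\t", index=False)

            stage = "de"
            deg_by_compartment: dict[str, dict[str, dict[str, list[str]]]] = {}
            de_tables: dict[tuple[str, str], pd.DataFrame] = {}
            for (cohort, comp), m in matrices.items():
                labels = table.table.loc[m.samples, "group"]
                if (labels == "LN").sum() < 2 or (labels == "LD").sum() < 2:
                    report["warnings"].append(f"de skipped for {cohort}/{comp}: group too small")
                    continue
                de = fit_moderated_t(
                    m, labels, case="LN", control="LD",
                    lfc_threshold=config.thresholds.lfc, alpha=config.thresholds.alpha,
                )
                de_tables[(cohort, comp)] = de
                de.drop(columns=["screen"]).assign(screen=de["screen"]).to_csv(
                    tmpdir / f"de_{cohort}_{comp}.tsv", sep="\t"
                )
                up, down = screen_degs(de, config.thresholds.lfc, config.thresholds.alpha)
                deg_by_compartment.setdefault(comp, {})[cohort] = {"up": up, "down": down}

            stage = "intersect"
            metabolic_union = registry.metabolic_union()
            candidates = {}
            for comp, lists in deg_by_compartment.items():
                if len(lists) < 2:
                    continue
                result = intersect_degs(
                    lists,
                    metabolic_union,
                    compartment=comp,
                    registry=registry,
                    de_tables={c: de_tables[(c, comp)] for c in lists},
                )
                result.as_frame().to_csv(
                    tmpdir / f"candidates_{comp}.tsv", sep="\t", index=False
                )
                (tmpdir / f"venn_{comp}.json").write_text(
                    json.dumps(result.venn_counts, indent=2)
                )
                candidates[comp] = {
                    "up": list(result.up_candidates),
                    "down": list(result.down_candidates),
                }
            report["candidates"] = candidates

            report["warnings"].extend(str(w.message) for w in caught)

        stage = "report"
        report["stages"] = [
            "build-sets", "load-data", "score", "compare", "correlate", "de", "intersect",
        ]
        report["elapsed_s"] = round(time.time() - t_start, 3)
        report["files"] = {
            p.name: _sha256(p) for p in sorted(tmpdir.iterdir()) if p.is_file()
        }
        (tmpdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))

        if outdir.exists():
            outdir.rmdir()
        tmpdir.rename(outdir)
    except Exception as exc:
        shutil.rmtree(tmpdir, ignore_errors=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report
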