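"""Ground-truthed synthetic renal-transcriptome cohorts.

The generator emulates the structure of the microarray study the pipeline
analyses: two independent cohorts, each profiled in the glomerular and
tubulointerstitial compartments, lupus nephritis (LN) cases versus living
donor (LD) controls. Expression is Gaussian on the log2 scale:

    x_gs = mu_g + pathway shift + DE effect + N(0, sd_g)

with per-gene baselines mu_g ~ U(4, 12) log2 units and sd_g ~ U(0.3, 1.0),
matching the range of normalized microarray intensities. Pathway effects
add a uniform shift delta to every gene of a named set in the LN samples
of one compartment; gene-level DE effects add |log2FC| ~ U(1.2, 3) to a
chosen number of background genes. Clinical covariates are generated from
the realized ferroptosis composite score (the latent disease-severity
axis): eGFR loads negatively; SCr, BUN, SLEDAI, C4 and the 4-HNE staining
score load positively. All outputs are consumable by the pipeline stages
unchanged, and the injected truth is recorded for recovery tests.

Everything is driven by one :func:`numpy.random.default_rng` seed; a fixed
config yields identical outputs across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, SampleTable
from .genesets import Registry
from .scoring import composite_score, zscore_genes

__all__ = [
    "PathwayEffect",
    "DEEffects",
    "CovariateModel",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate_cohort",
    "simulate_clinical",
]


@dataclass(frozen=True)
class PathwayEffect:
    """Add ``delta`` log2 units to every gene of ``set_name`` in LN samples
    of ``compartment``. ``heterogeneous`` draws per-gene deltas from
    U(0.5*delta, 1.5*delta) instead of a uniform shift."""

    set_name: str
    compartment: str
    delta: float
    heterogeneous: bool = False

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("pathway delta must be >= 0 (direction is up in LN)")


@dataclass(frozen=True)
class DEEffects:
    """Gene-level differential-expression effects in LN samples.

    ``n_up``/``n_down`` background DE genes are drawn from outside every
    registry set with |log2FC| ~ U(*lfc_range*). ``up_genes``/``down_genes``
    name additional explicit targets (these may be pathway members, e.g.
    metabolic genes for intersection experiments).
    """

    n_up: int = 30
    n_down: int = 30
    lfc_range: tuple[float, float] = (1.2, 3.0)
    up_genes: tuple[str, ...] | None = None
    down_genes: tuple[str, ...] | None = None
    explicit_lfc_range: tuple[float, float] | None = None  # None = lfc_range
    compartments: tuple[str, ...] | None = None  # None = all


@dataclass(frozen=True)
class CovariateModel:
    """Target Spearman correlations between covariates and the latent
    ferroptosis score. Signs follow the clinical direction: eGFR falls as
    ferroptosis rises, the rest rise with it."""

    targets: tuple[tuple[str, float], ...] = (
        ("eGFR", -0.6),
        ("SCr", 0.6),
        ("BUN", 0.6),
        ("SLEDAI", 0.5),
        ("C3", 0.2),
        ("C4", 0.4),
        ("HNE_score", 0.7),
    )

    def __post_init__(self) -> None:
        for name, rho in self.targets:
            if abs(rho) >= 1:
                raise ValueError(f"covariate {name!r}: target |rho| must be < 1")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 4000
    # cohort -> compartment -> (n_LN, n_LD)
    cohorts: tuple[tuple[str, tuple[tuple[str, tuple[int, int]], ...]], ...] = (
        ("cohort_a", (("glomerular", (10, 10)), ("tubulointerstitial", (10, 10)))),
        ("cohort_b", (("glomerular", (10, 10)), ("tubulointerstitial", (10, 10)))),
    )
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    baseline_sd_range: tuple[float, float] = (0.3, 1.0)
    pathway_effects: tuple[PathwayEffect, ...] = (
        PathwayEffect("ferroptosis", "glomerular", 1.0),
        PathwayEffect("iron_metabolism", "glomerular", 0.8),
        PathwayEffect("oxidative_phosphorylation", "glomerular", 0.6),
    )
    de_effects: DEEffects = DEEffects()
    covariate_model: CovariateModel = CovariateModel()
    latent_set: str = "ferroptosis"
    ln_class_probs: tuple[tuple[str, float], ...] = (
        ("II", 0.26), ("III", 0.26), ("IV", 0.42), ("V", 0.06),
    )
    p_treated: float = 0.7

    def __post_init__(self) -> None:
        for _, comps in self.cohorts:
            for comp, (n_ln, n_ld) in comps:
                if n_ln < 3 or n_ld < 3:
                    raise ValueError(f"{comp}: group sizes must be >= 3")


@dataclass
class SimTruth:
    pathway_effects: list[dict]
    true_up: dict[str, float]  # gene -> log2FC
    true_down: dict[str, float]
    covariate_targets: dict[str, float]
    realized_covariate_rho: dict[str, float]
    latent_set: str

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "pathway_effects": self.pathway_effects,
                    "true_up": self.true_up,
                    "true_down": self.true_down,
                    "covariate_targets": self.covariate_targets,
                    "realized_covariate_rho": self.realized_covariate_rho,
                    "latent_set": self.latent_set,
                },
                fh,
                indent=2,
            )


@dataclass
class SimResult:
    matrices: dict[tuple[str, str], ExpressionMatrix]  # (cohort, compartment)
    sample_table: SampleTable
    truth: SimTruth


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    n = len(x)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def simulate_clinical(
    latent: np.ndarray, model: CovariateModel, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate clinical covariates correlated with a latent score.

    The latent score is rank-normalized; each covariate is a Gaussian
    mixture r*z + sqrt(1−r²)*noise, where the Pearson weight r = 2
    sin(pi*rho_s/6) hits the target Spearman rho in expectation. Columns
    are then mapped to clinically plausible units (monotonically, so rank
    correlations are preserved); eGFR is truncated at 0.
    """
    latent = np.asarray(latent, dtype=float)
    if not np.isfinite(latent).all():
        raise ValueError("latent score must be finite")
    z = _rank_normalize(latent)
    n = len(z)
    units = {
        "eGFR": lambda c: np.clip(75.0 + 25.0 * c, 0.0, None),
        "SCr": lambda c: np.clip(1.3 + 0.7 * c, 0.2, None),
        "BUN": lambda c: np.clip(9.0 + 5.0 * c, 1.0, None),
        "SLEDAI": lambda c: np.clip(12.0 + 5.0 * c, 0.0, None),
        "C3": lambda c: np.clip(0.8 + 0.25 * c, 0.05, None),
        "C4": lambda c: np.clip(0.18 + 0.08 * c, 0.01, None),
        "HNE_score": lambda c: 1.0 / (1.0 + np.exp(-c)),
    }
    cols = {}
    for name, rho_s in model.targets:
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        raw = r * z + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
        cols[name] = units.get(name, lambda c: c)(raw)
    return pd.DataFrame(cols)


def simulate_cohort(config: SimConfig, registry: Registry) -> SimResult:
    """Simulate expression matrices, sample annotations and ground truth.

    The gene universe embeds every registry gene plus synthetic background
    genes up to ``n_genes``. Per-gene baselines are shared across cohorts
    and compartments; noise is i.i.d. Gaussian per sample.
    """
    rng = np.random.default_rng(config.seed)

    for eff in config.pathway_effects:
        if eff.set_name not in registry:
            raise KeyError(f"pathway effect names unknown set {eff.set_name!r}")

    registry_genes = sorted(set().union(*(gs.as_set() for gs in registry)))
    n_background = config.n_genes - len(registry_genes)
    if n_background < 0:
        raise ValueError(
            f"n_genes={config.n_genes} smaller than registry universe ({len(registry_genes)})"
        )
    background = [f"SIMG{i:05d}" for i in range(1, n_background + 1)]
    genes = pd.Index(registry_genes + background, name="gene")
    gene_pos = {g: i for i, g in enumerate(genes)}

    lo, hi = config.baseline_mean_range
    mu = rng.uniform(lo, hi, size=len(genes))
    lo, hi = config.baseline_sd_range
    sd = rng.uniform(lo, hi, size=len(genes))

    # gene-level DE truth (shared across cohorts so intersections replicate)
    de = config.de_effects
    explicit_up = list(de.up_genes or ())
    explicit_down = list(de.down_genes or ())
    for g in explicit_up + explicit_down:
        if g not in gene_pos:
            raise KeyError(f"DE effect names unknown gene {g!r}")
    bg_up: list[str] = []
    bg_down: list[str] = []
    if de.n_up + de.n_down > 0:
        pool = rng.permutation(background)
        if de.n_up + de.n_down > len(pool):
            raise ValueError("not enough background genes for requested DE effects")
        bg_up = list(pool[: de.n_up])
        bg_down = list(pool[de.n_up : de.n_up + de.n_down])
    ex_lo, ex_hi = de.explicit_lfc_range or de.lfc_range
    lfc_lo, lfc_hi = de.lfc_range
    true_up = {g: float(rng.uniform(ex_lo, ex_hi)) for g in sorted(explicit_up)}
    true_up.update({g: float(rng.uniform(lfc_lo, lfc_hi)) for g in sorted(bg_up)})
    true_down = {g: -float(rng.uniform(ex_lo, ex_hi)) for g in sorted(explicit_down)}
    true_down.update({g: -float(rng.uniform(lfc_lo, lfc_hi)) for g in sorted(bg_down)})

    # per-(effect, gene) pathway deltas, drawn once
    pathway_deltas: list[tuple[PathwayEffect, np.ndarray, np.ndarray]] = []
    for eff in config.pathway_effects:
        members = np.array([gene_pos[g] for g in registry[eff.set_name].genes])
        if eff.heterogeneous:
            deltas = rng.uniform(0.5 * eff.delta, 1.5 * eff.delta, size=len(members))
        else:
            deltas = np.full(len(members), eff.delta)
        pathway_deltas.append((eff, members, deltas))

    de_idx = np.array([gene_pos[g] for g in list(true_up) + list(true_down)], dtype=int)
    de_lfc = np.array(list(true_up.values()) + list(true_down.values()))

    class_names = [c for c, _ in config.ln_class_probs]
    class_p = np.array([p for _, p in config.ln_class_probs])
    class_p = class_p / class_p.sum()

    matrices: dict[tuple[str, str], ExpressionMatrix] = {}
    meta_rows: list[dict] = []
    sample_ids_by_stratum: dict[tuple[str, str], list[str]] = {}

    for cohort, comps in config.cohorts:
        for comp, (n_ln, n_ld) in comps:
            ids = [f"{cohort}_{comp[:4]}_LN{i:02d}" for i in range(1, n_ln + 1)] + [
                f"{cohort}_{comp[:4]}_LD{i:02d}" for i in range(1, n_ld + 1)
            ]
            is_ln = np.array([1] * n_ln + [0] * n_ld, dtype=float)
            x = mu[:, None] + sd[:, None] * rng.standard_normal((len(genes), len(ids)))
            for eff, members, deltas in pathway_deltas:
                if eff.compartment == comp:
                    x[np.ix_(members, np.flatnonzero(is_ln))] += deltas[:, None]
            if de.compartments is None or comp in de.compartments:
                x[np.ix_(de_idx, np.flatnonzero(is_ln))] += de_lfc[:, None]
            matrices[(cohort, comp)] = ExpressionMatrix(
                pd.DataFrame(x, index=genes, columns=ids)
            )
            sample_ids_by_stratum[(cohort, comp)] = ids
            for sid, ln in zip(ids, is_ln):
                row = {
                    "sample_id": sid,
                    "cohort": cohort,
                    "compartment": comp,
                    "group": "LN" if ln else "LD",
                    "ln_class": rng.choice(class_names, p=class_p) if ln else None,
                    "treated": bool(rng.random() < config.p_treated) if ln else None,
                }
                meta_rows.append(row)

    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    # clinical covariates from the realized latent (ferroptosis composite)
    realized: dict[str, list[float]] = {name: [] for name, _ in config.covariate_model.targets}
    if config.latent_set not in registry:
        raise KeyError(f"latent set {config.latent_set!r} not in registry")
    cov_frames = []
    for stratum, ids in sample_ids_by_stratum.items():
        z, _ = zscore_genes(matrices[stratum])
        latent = composite_score(z, registry[config.latent_set]).scores.to_numpy()
        cov = simulate_clinical(latent, config.covariate_model, rng)
        cov.index = pd.Index(ids, name="sample_id")
        cov_frames.append(cov)
        for name, _ in config.covariate_model.targets:
            rx = stats.rankdata(latent)
            ry = stats.rankdata(cov[name].to_numpy())
            realized[name].append(float(np.corrcoef(rx, ry)[0, 1]))
    covariates = pd.concat(cov_frames)
    meta = meta.join(covariates)

    truth = SimTruth(
        pathway_effects=[asdict(e) for e in config.pathway_effects],
        true_up=true_up,
        true_down=true_down,
        covariate_targets=dict(config.covariate_model.targets),
        realized_covariate_rho={k: float(np.mean(v)) for k, v in realized.items()},
        latent_set=config.latent_set,
    )
    return SimResult(matrices=matrices, sample_table=SampleTable(meta), truth=truth)
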