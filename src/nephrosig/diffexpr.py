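"""Two-group differential expression with an empirical-Bayes moderated t.

Per gene g the two-group contrast gives log2FC = mean1 − mean2 and a pooled
within-group variance s²_g on d_g = n1 + n2 − 2 df. Gene-wise variances are
shrunk toward a common prior: assuming s²_g | σ²_g ~ σ²_g·χ²_d/d and
1/σ²_g ~ χ²_d0/(d0·s0²), the posterior variance is

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g)

and the moderated statistic t_g = log2FC / (s̃_g·sqrt(1/n1 + 1/n2)) follows
a t distribution on d0 + d_g df under the null. The hyperparameters
(d0, s0²) are estimated by the method of moments on log s²_g using
digamma/trigamma identities (Smyth 2004 formulation); when the trigamma
equation has no positive solution the prior df is infinite and every
posterior variance equals s0².

Genes with zero pooled variance are retained (shrinkage regularizes them)
and flagged. Screening follows log2FC beyond ±1 with BH-adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "EBayesPrior",
    "estimate_prior",
    "fit_moderated_t",
    "bh_adjust",
    "screen_degs",
]


@dataclass(frozen=True)
class EBayesPrior:
    """Prior df d0 (may be inf) and prior variance s0² for variance shrinkage."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior df d0 must be >= 0")
        if not (np.isfinite(self.s0_sq) and self.s0_sq > 0):
            raise ValueError("prior variance s0_sq must be finite and > 0")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s_sq: np.ndarray, df: float) -> EBayesPrior:
    """Method-of-moments fit of (d0, s0²) from gene-wise sample variances.

    Moments of e_g = log s²_g − digamma(d/2) + log(d/2):
    E[e] = log s0² + digamma(d0/2) − log(d0/2) and
    Var[e] = trigamma(d/2) + trigamma(d0/2); the second is inverted for d0.
    Non-positive variances are excluded from estimation.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    ok = s_sq > 0
    if ok.sum() < 2:
        raise ValueError("need >=2 positive gene variances to estimate the prior")
    z = np.log(s_sq[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    n = e.size
    evar = np.sum((e - ebar) ** 2) / (n - 1)
    rhs = evar - special.polygamma(1, df / 2.0)
    if rhs > 0:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s0_sq = np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(ebar)
    return EBayesPrior(d0=float(d0), s0_sq=float(s0_sq))


def _posterior_var(s_sq: np.ndarray, df: float, prior: EBayesPrior) -> np.ndarray:
    if np.isinf(prior.d0):
        return np.full_like(np.asarray(s_sq, dtype=float), prior.s0_sq)
    return (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)


def fit_moderated_t(
    matrix,
    labels: pd.Series | Sequence[str],
    case: str,
    control: str,
    prior: EBayesPrior | None = None,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated-t differential expression, ``case`` minus ``control``.

    ``matrix`` is an :class:`~nephrosig.expression.ExpressionMatrix` (or a
    genes x samples DataFrame); ``labels`` assigns each sample to one of the
    two groups. ``prior`` overrides the estimated hyperparameters (d0 = 0
    recovers the ordinary pooled t; d0 = inf fixes every posterior variance
    at s0²). Returns a gene-indexed frame with log2fc, s2, s2_post, t, df,
    df_total, pvalue, adj_pvalue, zero_variance and screen columns.
    """
    df_vals = matrix.values if hasattr(matrix, "values") and not isinstance(matrix, pd.DataFrame) else pd.DataFrame(matrix)
    labels = pd.Series(labels, index=df_vals.columns) if not isinstance(labels, pd.Series) else labels
    idx1 = labels.index[labels == case]
    idx2 = labels.index[labels == control]
    n1, n2 = len(idx1), len(idx2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >=2 samples (got {case}:{n1}, {control}:{n2})")
    if df_vals.shape[0] < 2:
        raise ValueError("need >=2 genes")

    x1 = df_vals.loc[:, idx1].to_numpy()
    x2 = df_vals.loc[:, idx2].to_numpy()
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    lfc = m1 - m2
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    dof = n1 + n2 - 2
    s_sq = (ss1 + ss2) / dof

    if prior is None:
        prior = estimate_prior(s_sq, dof)
    s_post = _posterior_var(s_sq, dof, prior)

    se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    df_total = prior.d0 + dof
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)

    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "s2": s_sq,
            "df": float(dof),
            "s2_post": s_post,
            "t": t,
            "df_total": df_total,
            "pvalue": p,
            "zero_variance": s_sq == 0,
        },
        index=df_vals.index.rename("gene"),
    )
    out["adj_pvalue"] = bh_adjust(out["pvalue"].to_numpy())
    out["screen"] = "none"
    out.loc[(out["log2fc"] > lfc_threshold) & (out["adj_pvalue"] < alpha), "screen"] = "up"
    out.loc[(out["log2fc"] < -lfc_threshold) & (out["adj_pvalue"] < alpha), "screen"] = "down"
    out.attrs["prior"] = prior
    out.attrs["n1"], out.attrs["n2"] = n1, n2
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved).

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def screen_degs(
    results: pd.DataFrame, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Apply the DE screen: |log2FC| beyond the threshold and adj p < alpha.

    Returns (up, down) gene lists, each sorted by adjusted p, then
    decreasing |log2FC|, then gene name.
    """

    def _ranked(mask) -> list[str]:
        sub = results.loc[mask, ["adj_pvalue", "log2fc"]].reset_index(names="gene")
        sub["abs_lfc"] = -sub["log2fc"].abs()
        return sub.sort_values(["adj_pvalue", "abs_lfc", "gene"])["gene"].tolist()

    sig = results["adj_pvalue"] < alpha
    up = _ranked(sig & (results["log2fc"] > lfc_threshold))
    down = _ranked(sig & (results["log2fc"] < -lfc_threshold))
    return up, down
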