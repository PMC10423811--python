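"""Group comparisons of composite scores and clinical correlations.

The comparison rule follows common clinical-statistics practice: each
group is checked for normality with Shapiro–Wilk at alpha = 0.05; if both
groups pass, a two-sided Student's t-test (equal variances) is used and
groups are summarized as mean ± sd; otherwise a two-sided Mann–Whitney U
test is used (exact enumeration when n1 + n2 <= 12 with no ties, a
tie-corrected normal approximation otherwise) and groups are summarized as
median (range).

Correlations are Spearman's rho on midranks with the usual t-approximation
p-value; |rho| = 1 is reported as p = 0 with an exactness flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .expression import SampleTable
from .scoring import ScoreTable

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "compare_groups",
    "mann_whitney",
    "spearman_correlate",
    "stratified_compare",
    "GROUPINGS",
]

SHAPIRO_ALPHA = 0.05
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class ComparisonResult:
    set_name: str
    stratum: tuple
    grouping: str
    group1: str
    group2: str
    n1: int
    n2: int
    test: str  # "student_t" | "mann_whitney"
    statistic: float
    pvalue: float
    summary1: str
    summary2: str
    adj_pvalue: float | None = None

    def as_dict(self) -> dict:
        return {
            "set": self.set_name,
            "stratum": "/".join(map(str, self.stratum)),
            "grouping": self.grouping,
            "group1": self.group1,
            "group2": self.group2,
            "n1": self.n1,
            "n2": self.n2,
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "adj_pvalue": self.adj_pvalue,
            "summary1": self.summary1,
            "summary2": self.summary2,
        }


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    rho: float
    pvalue: float
    n: int
    exact: bool = False

    def as_dict(self) -> dict:
        return {
            "x": self.var_x,
            "y": self.var_y,
            "rho": self.rho,
            "pvalue": self.pvalue,
            "n": self.n,
            "exact": self.exact,
        }


def _is_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0:
        return False  # constant: Shapiro undefined, treat as non-normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue > SHAPIRO_ALPHA


def mann_whitney(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Mann–Whitney U with the small-sample exactness rule.

    Returns (U, p, method): the exact null distribution when n1 + n2 <= 12
    without ties, complete-enumeration permutation when small with ties,
    and the tie-corrected normal approximation otherwise.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    pooled = np.concatenate([g1, g2])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= EXACT_MW_MAX_N:
        method = "exact" if no_ties else stats.PermutationMethod(rng=0)
        name = "exact"
    else:
        method = "asymptotic"
        name = "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0)), name


def _summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{x.mean():.4g} ± {x.std(ddof=1):.4g}"
    return f"{np.median(x):.4g} ({x.min():.4g}–{x.max():.4g})"


def compare_groups(
    values,
    labels,
    *,
    set_name: str = "",
    stratum: tuple = (),
    grouping: str = "",
    group_order: Sequence[str] | None = None,
) -> ComparisonResult:
    """Compare a real-valued vector between two labelled groups.

    Each group needs n >= 3. The test family (Student t vs Mann–Whitney)
    is chosen by the per-group Shapiro–Wilk gate and recorded.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = list(group_order) if group_order is not None else sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {levels}")
    g1 = values[labels == levels[0]]
    g2 = values[labels == levels[1]]
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError(f"each group needs n>=3 (got {len(g1)}, {len(g2)})")

    if np.ptp(g1) == 0 and np.ptp(g2) == 0:
        # degenerate: no within-group variation at all
        warnings.warn("both groups constant; p set to 1", stacklevel=2)
        return ComparisonResult(
            set_name, tuple(stratum), grouping, levels[0], levels[1],
            len(g1), len(g2), "mann_whitney", np.nan, 1.0,
            _summary(g1, False), _summary(g2, False),
        )

    normal = _is_normal(g1) and _is_normal(g2)
    if normal:
        res = stats.ttest_ind(g1, g2, equal_var=True)
        test, statistic, p = "student_t", float(res.statistic), float(res.pvalue)
    else:
        statistic, p, _ = mann_whitney(g1, g2)
        test = "mann_whitney"
    return ComparisonResult(
        set_name, tuple(stratum), grouping, levels[0], levels[1],
        len(g1), len(g2), test, statistic, p,
        _summary(g1, normal), _summary(g2, normal),
    )


def spearman_correlate(x, y, *, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Spearman rank correlation on pairwise-complete observations.

    rho is the Pearson correlation of midranks; the two-sided p-value uses
    t = rho * sqrt((n−2)/(1−rho²)) on n−2 df. |rho| = 1 yields p = 0 with
    ``exact=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need n>=3 pairwise-complete observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input; correlation undefined")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) >= 1.0 - 1e-14:
        return CorrelationResult(var_x, var_y, float(np.sign(rho)), 0.0, n, exact=True)
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(var_x, var_y, rho, p, n)


# ---------------------------------------------------------------------------
# Stratified comparison panels

def _binary_from_group(table: pd.DataFrame, case: str, control: str) -> pd.Series:
    lab = table["group"].where(table["group"].isin([case, control]))
    return lab


def _grouping_ln_vs_ld(table: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    return _binary_from_group(table, "LN", "LD"), ["LN", "LD"]


def _grouping_egfr90(table: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    if "eGFR" not in table.columns:
        raise KeyError("grouping 'egfr90' needs an eGFR covariate")
    ln = table["group"] == "LN"
    lab = pd.Series(np.nan, index=table.index, dtype=object)
    lab[ln & (table["eGFR"] >= 90)] = "eGFR>=90"
    lab[ln & (table["eGFR"] < 90)] = "eGFR<90"
    return lab, ["eGFR<90", "eGFR>=90"]


def _grouping_treated(table: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    if "treated" not in table.columns:
        raise KeyError("grouping 'treated' needs a treated column")
    ln = table["group"] == "LN"
    lab = pd.Series(np.nan, index=table.index, dtype=object)
    lab[ln & (table["treated"] == True)] = "treated"  # noqa: E712 (NaN-safe)
    lab[ln & (table["treated"] == False)] = "untreated"  # noqa: E712
    return lab, ["treated", "untreated"]


def _grouping_class_iii_iv(table: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    if "ln_class" not in table.columns:
        raise KeyError("grouping 'class_iii_iv' needs an ln_class column")
    ln = table["group"] == "LN"
    lab = pd.Series(np.nan, index=table.index, dtype=object)
    lab[ln & table["ln_class"].isin(["III", "IV"])] = "class III/IV"
    lab[ln & table["ln_class"].notna() & ~table["ln_class"].isin(["III", "IV"])] = "other class"
    return lab, ["class III/IV", "other class"]


GROUPINGS: dict[str, Callable[[pd.DataFrame], tuple[pd.Series, list[str]]]] = {
    "ln_vs_ld": _grouping_ln_vs_ld,
    "egfr90": _grouping_egfr90,
    "treated": _grouping_treated,
    "class_iii_iv": _grouping_class_iii_iv,
}


def stratified_compare(
    score_tables: Mapping[tuple, ScoreTable],
    sample_table: SampleTable,
    groupings: Iterable[str] = ("ln_vs_ld",),
) -> list[ComparisonResult]:
    """Run a panel of score comparisons across strata and groupings.

    For each grouping (a named rule deriving two-level labels from the
    sample table, e.g. LN vs LD or eGFR >= 90 vs < 90), every set in every
    stratum's score table is compared; sides with n < 3 are skipped with a
    warning. BH adjustment is applied across the family of comparisons
    within each grouping panel and reported alongside raw p.
    """
    results: list[ComparisonResult] = []
    for grouping in groupings:
        if grouping not in GROUPINGS:
            raise KeyError(f"unknown grouping {grouping!r}; known: {sorted(GROUPINGS)}")
        panel: list[ComparisonResult] = []
        for stratum, st in score_tables.items():
            meta = sample_table.table.loc[st.scores.columns]
            labels, order = GROUPINGS[grouping](meta)
            mask = labels.notna()
            counts = labels.value_counts()
            if len(counts) < 2 or (counts < 3).any():
                warnings.warn(
                    f"grouping {grouping!r} in stratum {stratum}: a side has n<3, skipped",
                    stacklevel=2,
                )
                continue
            for set_name in st.scores.index:
                vals = st.scores.loc[set_name, mask].to_numpy()
                panel.append(
                    compare_groups(
                        vals,
                        labels[mask].to_numpy(),
                        set_name=set_name,
                        stratum=stratum,
                        grouping=grouping,
                        group_order=order,
                    )
                )
        if panel:
            adj = bh_adjust([r.pvalue for r in panel])
            panel = [
                ComparisonResult(**{**r.__dict__, "adj_pvalue": float(a)})
                for r, a in zip(panel, adj)
            ]
        results.extend(panel)
    return results
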