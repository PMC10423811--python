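"""Group comparisons (normality-gated t / Mann–Whitney) and Spearman rho."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nephrosig import ExpressionMatrix, SampleTable
from nephrosig.compare import (
    GROUPINGS,
    compare_groups,
    mann_whitney,
    spearman_correlate,
    stratified_compare,
)
from nephrosig.genesets import GeneSet
from nephrosig.scoring import score_all


def _mw_enumeration_oracle(g1, g2):
    """Two-sided exact MW p by enumerating all label assignments."""
    pooled = np.concatenate([g1, g2])
    n1 = len(g1)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(g2) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_separated_triples_exact_p(self):
        u, p, method = mann_whitney([1, 2, 3], [10, 11, 12])
        assert method == "exact"
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.10)
        assert p == pytest.approx(_mw_enumeration_oracle([1, 2, 3], [10, 11, 12]))

    def test_identical_groups_give_p_one(self):
        _, p, _ = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle_small_untied(self, rng):
        for _ in range(10):
            g1 = rng.normal(0, 1, 4)
            g2 = rng.normal(0.8, 1, 5)
            _, p, method = mann_whitney(g1, g2)
            assert method == "exact"
            assert p == pytest.approx(_mw_enumeration_oracle(g1, g2), abs=1e-12)

    def test_exact_and_asymptotic_agree_at_n6_plus_6(self, rng):
        for _ in range(50):
            g1, g2 = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
            pe = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="exact").pvalue
            pa = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic").pvalue
            assert abs(pe - pa) <= 0.02


class TestCompareGroups:
    def test_gaussian_samples_use_student_t(self, rng):
        vals = np.r_[rng.normal(0, 1, 50), rng.normal(0.3, 1, 50)]
        res = compare_groups(vals, ["a"] * 50 + ["b"] * 50)
        assert res.test == "student_t"
        assert "±" in res.summary1

    def test_skewed_samples_use_mann_whitney(self, rng):
        vals = np.r_[rng.exponential(1, 30) ** 2, rng.exponential(2, 30) ** 2]
        res = compare_groups(vals, ["a"] * 30 + ["b"] * 30)
        assert res.test == "mann_whitney"
        assert "(" in res.summary1  # median (range)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n>=3"):
            compare_groups([1, 2, 3, 4], ["a", "a", "b", "b"])

    def test_both_groups_constant_warns_p_one(self):
        with pytest.warns(UserWarning, match="constant"):
            res = compare_groups([5.0] * 3 + [5.0] * 3, ["a"] * 3 + ["b"] * 3)
        assert res.pvalue == 1.0

    def test_type_one_error_near_alpha_under_gaussian_null(self):
        # group sizes mimic a 14-case / 7-control whole-kidney cohort
        reject = 0
        n_reps = 400
        for i in range(n_reps):
            r = np.random.default_rng(5000 + i)
            vals = r.normal(0, 1, 21)
            res = compare_groups(vals, ["a"] * 14 + ["b"] * 7)
            reject += res.pvalue < 0.05
        assert 0.02 <= reject / n_reps <= 0.09  # loose band at this MC budget


class TestSpearman:
    def test_perfect_antitone(self):
        r = spearman_correlate([1, 2, 3], [3, 2, 1])
        assert r.rho == -1.0 and r.pvalue == 0.0 and r.exact

    def test_hand_computed_example(self):
        r = spearman_correlate([1, 2, 3, 4], [1, 3, 2, 4])
        assert r.rho == pytest.approx(0.8)

    def test_matches_scipy_reference(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        r = spearman_correlate(x, y)
        ref = stats.spearmanr(x, y)
        assert r.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert r.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(deadline=None, max_examples=100)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 5)), min_size=4, max_size=30
        )
    )
    def test_midrank_oracle_on_tied_data(self, data):
        x = np.array([a for a, _ in data], dtype=float)
        y = np.array([b for _, b in data], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        # brute-force midranks: average position of equal values
        def midrank(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks

        rx, ry = midrank(x), midrank(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_correlate(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        base = spearman_correlate(x, y).rho
        assert spearman_correlate(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman_correlate(x, y**3).rho == pytest.approx(base, abs=1e-12)

    def test_pairwise_complete_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 1.0, 3.0, 5.0, 4.0]
        assert spearman_correlate(x, y).n == 4

    @pytest.mark.parametrize(
        "x, y, match",
        [
            ([1, 2], [1, 2], "n>=3"),
            ([1, 1, 1], [1, 2, 3], "zero variance"),
        ],
    )
    def test_degenerate_inputs_rejected(self, x, y, match):
        with pytest.raises(ValueError, match=match):
            spearman_correlate(x, y)


def _scored_cohort(rng, n_sets=7, delta=0.0):
    genes = [f"G{i}" for i in range(n_sets * 10)]
    sets = [GeneSet(f"set{k}", tuple(genes[k * 10 : (k + 1) * 10])) for k in range(n_sets)]
    rows, frames = [], []
    for comp in ("glomerular", "tubulointerstitial"):
        ids = [f"{comp[:4]}{i}" for i in range(16)]
        x = rng.normal(8, 1, (len(genes), 16))
        if delta and comp == "glomerular":
            x[:10, :8] += delta  # set0 genes up in LN
        frames.append(pd.DataFrame(x, index=genes, columns=ids))
        for k, sid in enumerate(ids):
            rows.append(
                {
                    "sample_id": sid,
                    "cohort": "c1",
                    "compartment": comp,
                    "group": "LN" if k < 8 else "LD",
                    "eGFR": 100.0 + k,
                }
            )
    table = SampleTable(pd.DataFrame(rows).set_index("sample_id"))
    matrix = ExpressionMatrix(pd.concat(frames, axis=1))
    return score_all(matrix, table, sets), table


class TestStratifiedCompare:
    def test_panel_size_is_sets_times_strata(self, rng):
        tables, meta = _scored_cohort(rng)
        results = stratified_compare(tables, meta, ["ln_vs_ld"])
        assert len(results) == 14  # 7 sets x 2 compartments
        assert all(r.adj_pvalue is not None for r in results)

    def test_adjusted_p_at_least_raw(self, rng):
        tables, meta = _scored_cohort(rng)
        for r in stratified_compare(tables, meta, ["ln_vs_ld"]):
            assert r.adj_pvalue >= r.pvalue - 1e-12

    def test_degenerate_grouping_skipped_with_warning(self, rng):
        tables, meta = _scored_cohort(rng)  # all eGFR >= 90
        with pytest.warns(UserWarning, match="skipped"):
            results = stratified_compare(tables, meta, ["egfr90"])
        assert results == []

    def test_unknown_grouping_rejected(self, rng):
        tables, meta = _scored_cohort(rng)
        with pytest.raises(KeyError, match="unknown grouping"):
            stratified_compare(tables, meta, ["bogus"])

    def test_compartment_specific_shift_detected_only_in_glomerular(self):
        hits_glom = hits_tub = 0
        n_reps = 40
        for i in range(n_reps):
            rng = np.random.default_rng(9000 + i)
            tables, meta = _scored_cohort(rng, delta=1.0)
            results = stratified_compare(tables, meta, ["ln_vs_ld"])
            for r in results:
                if r.set_name == "set0" and r.pvalue < 0.05:
                    if r.stratum[1] == "glomerular":
                        hits_glom += 1
                    else:
                        hits_tub += 1
        assert hits_glom >= 0.9 * n_reps
        assert hits_tub <= 0.2 * n_reps

    def test_known_groupings_registered(self):
        assert {"ln_vs_ld", "egfr90", "treated", "class_iii_iv"} <= set(GROUPINGS)
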