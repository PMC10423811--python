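"""Moderated-t differential expression: limits, shrinkage, BH, screening."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nephrosig.diffexpr import (
    EBayesPrior,
    bh_adjust,
    estimate_prior,
    fit_moderated_t,
    screen_degs,
)


def _null_matrix(rng, n_genes=200, n1=5, n2=5, scale=True):
    x = rng.normal(0, 1, size=(n_genes, n1 + n2))
    if scale:
        x *= rng.uniform(0.5, 2.0, size=(n_genes, 1))
    cols = [f"A{i}" for i in range(n1)] + [f"B{i}" for i in range(n2)]
    df = pd.DataFrame(x, index=[f"G{i:04d}" for i in range(n_genes)], columns=cols)
    labels = pd.Series(["case"] * n1 + ["ctrl"] * n2, index=cols)
    return df, labels


class TestModeratedT:
    def test_d0_zero_recovers_ordinary_pooled_t(self, rng):
        df, labels = _null_matrix(rng, n_genes=500)
        res = fit_moderated_t(df, labels, "case", "ctrl", prior=EBayesPrior(0.0, 1.0))
        ref = stats.ttest_ind(
            df.loc[:, labels == "case"], df.loc[:, labels == "ctrl"], axis=1, equal_var=True
        )
        np.testing.assert_allclose(res["t"].to_numpy(), ref.statistic, atol=1e-8)
        np.testing.assert_allclose(res["pvalue"].to_numpy(), ref.pvalue, atol=1e-8)

    def test_d0_infinite_pins_posterior_variance_at_prior(self, rng):
        df, labels = _null_matrix(rng)
        res = fit_moderated_t(df, labels, "case", "ctrl", prior=EBayesPrior(np.inf, 0.7))
        assert (res["s2_post"] == 0.7).all()

    def test_shrinkage_is_convex_combination(self, rng):
        df, labels = _null_matrix(rng)
        res = fit_moderated_t(df, labels, "case", "ctrl")
        prior = res.attrs["prior"]
        lo = np.minimum(res["s2"], prior.s0_sq)
        hi = np.maximum(res["s2"], prior.s0_sq)
        assert ((res["s2_post"] >= lo - 1e-12) & (res["s2_post"] <= hi + 1e-12)).all()

    def test_null_pvalues_uniform(self, rng):
        df, labels = _null_matrix(np.random.default_rng(7), n_genes=2000, scale=False)
        res = fit_moderated_t(df, labels, "case", "ctrl")
        ks = stats.kstest(res["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_zero_variance_gene_regularized(self, rng):
        df, labels = _null_matrix(rng, n_genes=50)
        df.iloc[0] = 3.0  # constant in both groups
        res = fit_moderated_t(df, labels, "case", "ctrl")
        assert res["zero_variance"].iloc[0]
        assert res["s2_post"].iloc[0] > 0
        assert np.isfinite(res["t"].iloc[0])

    def test_small_group_rejected(self, rng):
        df, labels = _null_matrix(rng, n1=1, n2=5)
        with pytest.raises(ValueError, match=">=2 samples"):
            fit_moderated_t(df, labels, "case", "ctrl")

    def test_monotone_in_lfc_at_fixed_variance(self, rng):
        df, labels = _null_matrix(rng, n_genes=100)
        res = fit_moderated_t(df, labels, "case", "ctrl", prior=EBayesPrior(np.inf, 1.0))
        order = np.argsort(np.abs(res["log2fc"].to_numpy()))
        assert (np.diff(np.abs(res["t"].to_numpy()[order])) >= -1e-12).all()

    def test_agrees_with_limma_reference(self, rng, tmp_path):
        """Independent oracle: Bioconductor limma on the same matrix."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript expected on PATH for the limma cross-check")
        df, labels = _null_matrix(np.random.default_rng(42), n_genes=200)
        df.iloc[:20, :5] += 1.5
        mat_path = tmp_path / "mat.tsv"
        out_path = tmp_path / "limma.tsv"
        df.to_csv(mat_path, sep="\t")
        rcode = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{mat_path}", row.names=1))
        design <- cbind(Intercept=1, case=c(rep(1,5), rep(0,5)))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t=fit$t[,"case"], p=fit$p.value[,"case"], d0=fit$df.prior, s0=fit$s2.prior)
        write.table(out, "{out_path}", sep="\\t", quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        ref = pd.read_csv(out_path, sep="\t")
        res = fit_moderated_t(df, labels, "case", "ctrl")
        prior = res.attrs["prior"]
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-5)
        assert prior.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-5)
        np.testing.assert_allclose(res["t"].to_numpy(), ref["t"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(res["pvalue"].to_numpy(), ref["p"].to_numpy(), atol=1e-8)


class TestEstimatePrior:
    def test_recovers_large_d0_for_homogeneous_variances(self, rng):
        # all true variances equal -> little spread in log s2 -> large/infinite d0
        s2 = stats.chi2.rvs(8, size=5000, random_state=1) / 8
        prior = estimate_prior(s2, df=8)
        assert prior.d0 > 20
        assert prior.s0_sq == pytest.approx(1.0, rel=0.1)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            EBayesPrior(-1.0, 1.0)
        with pytest.raises(ValueError):
            EBayesPrior(1.0, 0.0)


def _bh_oracle(p):
    """Brute-force step-up from the definition: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    @settings(deadline=None, max_examples=100)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_array_equal(bh_adjust(p), _bh_oracle(p))

    @settings(deadline=None, max_examples=50)
    @given(
        p=st.lists(st.floats(0.0, 0.99, allow_nan=False), min_size=2, max_size=20),
        idx=st.integers(0, 100),
        bump=st.floats(0.001, 0.3),
    )
    def test_monotone_raising_a_p_never_lowers_adjusted(self, p, idx, bump):
        p = np.asarray(p)
        p2 = p.copy()
        i = idx % len(p)
        p2[i] = min(1.0, p2[i] + bump)
        assert (bh_adjust(p2) >= bh_adjust(p) - 1e-12).all()

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-15).all()

    @pytest.mark.parametrize("bad", [[-0.1], [1.2], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


class TestScreen:
    def _frame(self):
        return pd.DataFrame(
            {
                "log2fc": [1.5, 0.9, -1.2, 2.5, -0.5],
                "adj_pvalue": [0.01, 0.001, 0.04, 0.2, 0.01],
            },
            index=pd.Index(["A", "B", "C", "D", "E"], name="gene"),
        )

    def test_thresholds_applied_to_both_axes(self):
        up, down = screen_degs(self._frame())
        assert up == ["A"]  # fc 1.5, p .01
        assert down == ["C"]  # fc -1.2, p .04
        # B fails fold-change despite tiny p; D fails p; E fails both

    def test_lists_disjoint_and_sorted_by_adj_p(self, rng):
        n = 200
        frame = pd.DataFrame(
            {
                "log2fc": rng.normal(0, 2, n),
                "adj_pvalue": rng.uniform(0, 0.2, n),
            },
            index=pd.Index([f"G{i}" for i in range(n)], name="gene"),
        )
        up, down = screen_degs(frame)
        assert not set(up) & set(down)
        ps = frame.loc[up, "adj_pvalue"].to_numpy()
        assert (np.diff(ps) >= 0).all()
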