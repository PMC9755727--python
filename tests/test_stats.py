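import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tractstrata.datamodel import ValidationError
from tractstrata.stats import (
    ancova_compare,
    cohens_d,
    correlate,
    fdr_bh,
    paired_compare,
)


def bh_stepup_reference(p):
    """Direct textbook step-up: q_i = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestAncova:
    def test_three_group_toy_f_is_exactly_3(self):
        y = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], dtype=float)
        g = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = ancova_compare(y, g)
        assert res.f_stat == pytest.approx(3.0, abs=1e-12)
        assert (res.df_num, res.df_den) == (2, 6)

    def test_no_covariates_reduces_to_one_way_anova(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        res = ancova_compare(y, g)
        f_ref, p_ref = sps.f_oneway(y[:10], y[10:20], y[20:])
        assert res.f_stat == pytest.approx(f_ref, rel=1e-10)
        assert res.p_omnibus == pytest.approx(p_ref, rel=1e-10)

    def test_orthogonal_covariate_leaves_group_f_almost_unchanged(self):
        # covariate orthogonal to both y and the group dummies only costs df
        rng = np.random.default_rng(1)
        y = rng.normal(size=12)
        g = np.repeat(["a", "b", "c"], 4)
        dummies = np.column_stack([g == lev for lev in ("b", "c")]).astype(float)
        X = np.column_stack([np.ones(12), dummies, y])
        z = rng.normal(size=12)
        z -= X @ np.linalg.lstsq(X, z, rcond=None)[0]  # residualize
        res0 = ancova_compare(y, g)
        res1 = ancova_compare(y, g, pd.DataFrame({"z": z}))
        # identical sums of squares; F shifts only via df_den bookkeeping
        assert res1.df_den == res0.df_den - 1
        assert res1.f_stat * res0.df_den / res1.df_den == pytest.approx(
            res0.f_stat, rel=1e-8)

    def test_covariate_adjustment_changes_inference(self):
        # group means differ purely through an age trend: adjusting removes it
        rng = np.random.default_rng(2)
        age = np.concatenate([rng.uniform(20, 30, 15), rng.uniform(50, 60, 15)])
        y = 0.5 * age + rng.normal(0, 1.0, 30)
        g = np.repeat(["young", "old"], 15)
        raw = ancova_compare(y, g)
        adj = ancova_compare(y, g, pd.DataFrame({"age": age}))
        assert raw.p_omnibus < 1e-6
        assert adj.p_omnibus > 0.01

    def test_sex_covariate_is_factor_coded(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=18)
        g = np.repeat(["a", "b", "c"], 6)
        cov = pd.DataFrame({"sex": np.tile(["F", "M"], 9)})
        res = ancova_compare(y, g, cov)
        assert any("sex" in c for c in res.covariates)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            ancova_compare(np.ones(9), np.repeat(["a", "b", "c"], 3))

    def test_small_group_rejected(self):
        y = np.arange(5.0)
        g = np.array(["a", "a", "a", "b", "b"])
        with pytest.raises(ValidationError, match="fewer than 3"):
            ancova_compare(y, g)

    def test_contrast_estimates_and_d_share_sign(self):
        rng = np.random.default_rng(4)
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(2, 1, 10),
                            rng.normal(4, 1, 10)])
        g = np.repeat(["a", "b", "c"], 10)
        res = ancova_compare(y, g, pd.DataFrame({"age": rng.uniform(20, 60, 30)}))
        for c in res.contrasts:
            assert np.sign(c.cohens_d) == np.sign(c.estimate)

    def test_null_type_one_error_rate(self):
        # seeded null simulation: ~5% of omnibus tests reject at 0.05
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 400
        for _ in range(reps):
            y = rng.normal(size=30)
            g = np.repeat(["a", "b", "c"], 10)
            if ancova_compare(y, g).p_omnibus < 0.05:
                rejections += 1
        lo, hi = sps.binom.interval(0.999, reps, 0.05)
        assert lo <= rejections <= hi


class TestCohensD:
    def test_unit_pooled_sd_fixture(self):
        assert cohens_d([0, 2], [-1, 1]) == pytest.approx(1.0)

    def test_identical_samples_give_zero(self):
        x = [1.0, 2.0, 3.0]
        assert cohens_d(x, x) == 0.0

    def test_matches_direct_formula_on_random_samples(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(1, 2, 15), rng.normal(0, 1.5, 20)
        ss = np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)
        pooled = np.sqrt(ss / 35)
        assert cohens_d(x, y) == pytest.approx((x.mean() - y.mean()) / pooled)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            cohens_d([1, 1], [1, 1])


class TestFdrBH:
    def test_classic_linear_ladder_all_collapse_to_max(self):
        adj = fdr_bh([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(adj, [0.05] * 5)

    def test_single_p_identity(self):
        np.testing.assert_allclose(fdr_bh([0.5]), [0.5])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.randoms())
    def test_matches_reference_and_is_permutation_equivariant(self, p, rnd):
        adj = fdr_bh(p)
        np.testing.assert_allclose(adj, bh_stepup_reference(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-15).all()
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adj_perm = fdr_bh([p[i] for i in perm])
        np.testing.assert_allclose(adj_perm, adj[perm], atol=1e-12)

    def test_rejection_set_matches_classical_stepup(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            for alpha in (0.01, 0.05, 0.2):
                reject_adj = fdr_bh(p) <= alpha
                m = p.size
                order = np.argsort(p)
                thresh = alpha * np.arange(1, m + 1) / m
                below = np.flatnonzero(p[order] <= thresh)
                reject_ref = np.zeros(m, dtype=bool)
                if below.size:
                    reject_ref[order[: below.max() + 1]] = True
                np.testing.assert_array_equal(reject_adj, reject_ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_bh([0.5, 1.2])


class TestCorrelate:
    def test_exact_linear_gives_pearson_one(self):
        x = np.arange(10.0)
        rec = correlate(x, 2 * x + 1, method="pearson")
        assert rec.r == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman_vs_pearson(self):
        x = np.linspace(-2, 2, 15)
        y = -(x ** 3)
        assert correlate(x, y, "spearman").r == pytest.approx(-1.0)
        assert correlate(x, y, "pearson").r > -1.0

    def test_sampling_distribution_around_true_rho(self):
        rng = np.random.default_rng(8)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=5000)
        rec = correlate(z[:, 0], z[:, 1], "pearson")
        assert 0.55 < rec.r < 0.65

    def test_pearson_invariant_under_positive_affine_maps(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=30), rng.normal(size=30)
        base = correlate(x, y, "pearson").r
        assert correlate(3 * x + 7, 0.5 * y - 2, "pearson").r == pytest.approx(base)

    def test_auto_method_prefers_spearman_for_heavy_tails(self):
        rng = np.random.default_rng(10)
        x = rng.standard_cauchy(200)
        y = rng.normal(size=200)
        assert correlate(x, y, "auto").method == "spearman"
        xn, yn = rng.normal(size=200), rng.normal(size=200)
        assert correlate(xn, yn, "auto").method == "pearson"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            correlate([1, 1, 1], [1, 2, 3])


class TestPairedCompare:
    def test_identity_followup_gives_t0_p1(self):
        b = [1.0, 2.0, 3.0, 4.0]
        res = paired_compare(b, b)
        assert (res.t_stat, res.p) == (0.0, 1.0)

    def test_constant_nonzero_differences_flagged_degenerate(self):
        res = paired_compare([0, 0, 0, 0], [1, 1, 1, 1])
        assert res.degenerate_variance
        assert res.p == 0.0 and np.isinf(res.t_stat)

    def test_matches_scipy_on_shifted_pairs(self):
        rng = np.random.default_rng(11)
        b = rng.normal(size=20)
        f = b + rng.normal(0.5, 1.0, 20)
        res = paired_compare(b, f)
        t_ref, p_ref = sps.ttest_rel(f, b)
        assert res.t_stat == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)
        assert res.mean_difference == pytest.approx((f - b).mean())

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            paired_compare([1, 2], [2, 3])
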