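import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dvx import (
    bh_adjust,
    brown_forsythe_arrays,
    brown_forsythe_test,
    compute_group_stats,
    mad,
    mad_ratio_with_ci,
)


def bh_oracle(pvalues):
    """Brute-force BH: adj for p_(i) is the min over the tail of p_(j)*m/j."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        tail = [
            p[j] * m / r
            for r, j in enumerate(order, start=1)
            if r >= rank_pos
        ]
        adj[i] = min(1.0, min(tail))
    return adj


class TestMad:
    def test_hand_computed(self):
        assert mad([1, 2, 3, 4, 5]) == 1.0

    def test_constant_list_is_zero(self):
        assert mad([4.2, 4.2, 4.2]) == 0.0

    def test_scale_constant_is_linear(self):
        x = [3.0, 1.0, 7.0, 2.0]
        assert mad(x, 1.4826) == pytest.approx(1.4826 * mad(x))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad([])


class TestGroupStats:
    def test_hand_computed_summary(self, two_group_matrix):
        matrix, annotation = two_group_matrix
        table = compute_group_stats(matrix, annotation, ["A"])
        row = table.iloc[0]
        assert row["n"] == 3
        assert row["mean"] == pytest.approx(10.0)
        assert row["sd"] == pytest.approx(2.0)
        assert row["cv"] == pytest.approx(0.2)
        assert row["mad"] == pytest.approx(2.0)

    def test_singleton_group_flagged_undefined(self, two_group_matrix):
        matrix, annotation = two_group_matrix
        sub = annotation.table.iloc[[0]]
        from dvx import SampleAnnotation

        table = compute_group_stats(matrix, SampleAnnotation(sub), ["A"])
        assert np.isnan(table["sd"].iloc[0])
        assert np.isnan(table["mad"].iloc[0])

    def test_nonpositive_mean_leaves_cv_undefined(self):
        from dvx import ExpressionMatrix, SampleAnnotation
        import pandas as pd

        matrix = ExpressionMatrix(
            ["G1"], ["S1", "S2", "S3"], np.array([[-2.0, 0.0, 2.0]])
        )
        annotation = SampleAnnotation(
            pd.DataFrame(
                {"sample_id": ["S1", "S2", "S3"], "group_label": "A",
                 "dataset_id": ""}
            )
        )
        table = compute_group_stats(matrix, annotation, ["A"])
        assert np.isnan(table["cv"].iloc[0])
        assert table["sd"].iloc[0] > 0
        assert table["mad"].iloc[0] > 0

    def test_unknown_group_and_missing_samples_error(self, two_group_matrix):
        matrix, annotation = two_group_matrix
        with pytest.raises(ValueError):
            compute_group_stats(matrix, annotation, ["missing-group"])


class TestBrownForsythe:
    def test_hand_anova_on_absolute_deviations(self):
        # medians 3 and 30; deviations (2,1,0,1,2) and (20,10,0,10,20);
        # SSB = 291.6, SSW = 282.8 on (1, 8) df.
        result = brown_forsythe_test([[1, 2, 3, 4, 5], [10, 20, 30, 40, 50]])
        expected_F = (291.6 / 1) / (282.8 / 8)
        assert result.F == pytest.approx(expected_F, rel=1e-12)
        assert (result.df1, result.df2) == (1, 8)
        assert result.p == pytest.approx(sps.f.sf(expected_F, 1, 8), rel=1e-12)

    def test_identical_spread_gives_zero_F(self):
        result = brown_forsythe_test([[1, 2, 3], [11, 12, 13], [21, 22, 23]])
        assert result.F == 0.0
        assert result.p == 1.0

    def test_constant_groups_degenerate(self):
        result = brown_forsythe_test([[5, 5, 5], [9, 9, 9]])
        assert result.degenerate
        assert result.p == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            brown_forsythe_test([[1], [2, 3]])

    @given(shift=st.floats(-50, 50), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_location_shift_and_relabel_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 8), rng.normal(0, 3, 9)
        base = brown_forsythe_test([a, b])
        shifted = brown_forsythe_test([a + shift, b])
        relabeled = brown_forsythe_test([b, a])
        assert shifted.F == pytest.approx(base.F, rel=1e-9, abs=1e-12)
        assert relabeled.F == pytest.approx(base.F, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_group_F_equals_squared_t_on_deviations(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 2, 12)
        za = np.abs(a - np.median(a))
        zb = np.abs(b - np.median(b))
        t, _ = sps.ttest_ind(za, zb, equal_var=True)
        result = brown_forsythe_test([a, b])
        assert result.F == pytest.approx(t**2, rel=1e-9)

    def test_vectorized_matches_scipy_levene(self):
        rng = np.random.default_rng(3)
        t = rng.normal(0, 1, (200, 15))
        r = rng.normal(0, 2, (200, 20))
        F, p, _ = brown_forsythe_arrays(t, r)
        for i in range(0, 200, 17):
            W, pv = sps.levene(t[i], r[i], center="median")
            assert F[i] == pytest.approx(W, rel=1e-10)
            assert p[i] == pytest.approx(pv, rel=1e-10)

    def test_null_rejection_rate_near_nominal(self):
        """Equal-variance Normal null, n=30/group: rejection rate at
        alpha=0.05 within 3 Monte-Carlo SEs of the nominal level."""
        rng = np.random.default_rng(0)
        n_sim = 2000
        t = rng.normal(0, 1, (n_sim, 30))
        r = rng.normal(0, 1, (n_sim, 30))
        _, p, _ = brown_forsythe_arrays(t, r)
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 3 * se


class TestMadRatio:
    def test_identity_ratio_with_covering_ci(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        est = mad_ratio_with_ci(x, x, seed=1)
        assert est.ratio == 1.0
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_hand_computed_tenfold_ratio(self):
        est = mad_ratio_with_ci(
            [10, 20, 30, 40, 50], [1, 2, 3, 4, 5], seed=3
        )
        assert est.ratio == 10.0
        assert est.ci_low <= 10.0 <= est.ci_high

    def test_zero_reference_mad_rejected(self):
        with pytest.raises(ValueError, match="reference MAD"):
            mad_ratio_with_ci([1, 2, 3], [5, 5, 5], seed=0)

    def test_zero_test_mad_flagged(self):
        est = mad_ratio_with_ci([5, 5, 5], [1, 2, 3], seed=0)
        assert est.ratio == 0.0
        assert est.warning

    def test_seeded_bootstrap_reproducible(self):
        rng = np.random.default_rng(9)
        t, r = rng.normal(0, 2, 40), rng.normal(0, 1, 40)
        a = mad_ratio_with_ci(t, r, seed=123)
        b = mad_ratio_with_ci(t, r, seed=123)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    @pytest.mark.parametrize("seed", range(4))
    def test_ratio_invariant_to_scale_constant(self, seed):
        rng = np.random.default_rng(seed)
        t, r = rng.normal(0, 2, 20), rng.normal(0, 1, 20)
        a = mad_ratio_with_ci(t, r, method="asymptotic-log", scale_constant=1.0)
        b = mad_ratio_with_ci(t, r, method="asymptotic-log", scale_constant=1.4826)
        assert a.ratio == pytest.approx(b.ratio, rel=1e-12)

    def test_asymptotic_log_interval_symmetric_on_log_scale(self):
        rng = np.random.default_rng(2)
        t, r = rng.normal(0, 2, 30), rng.normal(0, 1, 30)
        est = mad_ratio_with_ci(t, r, method="asymptotic-log")
        assert est.ci_low * est.ci_high == pytest.approx(est.ratio**2, rel=1e-9)


class TestBHAdjust:
    def test_hand_computed_examples(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust([0.001, 0.5]), [0.002, 0.5])
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=6)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_min_over_tail_oracle(self, pvalues):
        np.testing.assert_allclose(bh_adjust(pvalues), bh_oracle(pvalues),
                                   rtol=1e-12, atol=1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 200)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
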