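"""Fisher-Pitman permutation tests, BH adjustment, variance preconditions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from paleobrain.errors import ValidationError
from paleobrain.group_tests import (
    benjamini_hochberg,
    fp_ksample,
    fp_ksample_exact,
    fp_pairwise,
    variance_checks,
)


class TestKSample:
    def test_constant_values_degenerate(self):
        res = fp_ksample([3.0] * 38, ["a"] * 20 + ["b"] * 18)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.df == 1

    def test_two_group_enumeration_example(self):
        """Groups {1,2} vs {3,4}: exact p over C(4,2)=6 assignments is 1/3."""
        p_exact = fp_ksample_exact([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert p_exact == pytest.approx(1 / 3)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            fp_ksample([1.0, 2.0], ["a", "a"])

    @pytest.mark.parametrize("seed", range(25))
    def test_asymptotic_close_to_exact_in_the_tail(self, seed):
        """Chi^2 p agrees with full enumeration where decisions are made.

        The permutation null at n = 10 is discrete (252 atoms for two
        balanced groups), so the continuous chi^2 approximation can sit a
        whole atom away from the exact tail in the centre of the
        distribution; in the rejection-relevant tail (p <= 0.1) the two
        agree within 0.05 on balanced two-group fixtures.
        """
        rng = np.random.default_rng(seed)
        groups = np.array(["a"] * 5 + ["b"] * 5)
        values = rng.normal(size=10) + (groups == "a") * rng.uniform(0, 2.0)
        asym = fp_ksample(values, groups)
        exact = fp_ksample_exact(values, groups)
        if min(asym.p_value, exact) <= 0.1:
            assert abs(asym.p_value - exact) < 0.05
        else:
            assert abs(asym.p_value - exact) < 0.35  # centre: one-atom slack

    def test_location_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=25)
        g = np.array(["a", "b", "c", "d", "e"] * 5)
        base = fp_ksample(v, g).statistic
        shifted = fp_ksample(v + 100.0, g).statistic
        scaled = fp_ksample(4.0 * v - 2.0, g).statistic
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_df_is_groups_minus_one(self, default_dataset):
        traits = default_dataset.traits
        from paleobrain.allometry import compute_percentages

        pct = compute_percentages(traits)
        res = fp_ksample(pct.neo_pct, traits.column("locomotion"))
        assert res.df == 4
        assert res.statistic > 0


class TestPairwise:
    def test_identical_groups_give_p_one(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array(["a"] * 3 + ["b"] * 3)
        res = fp_pairwise(v, g)
        assert res[0].statistic == pytest.approx(0.0)
        assert res[0].p_value == 1.0

    def test_ten_pairs_for_five_groups(self, default_dataset):
        traits = default_dataset.traits
        from paleobrain.allometry import compute_percentages

        pct = compute_percentages(traits)
        res = fp_pairwise(pct.neo_pct, traits.column("locomotion"))
        assert len(res) == 10
        for r in res:
            assert r.p_adjusted >= r.p_value - 1e-15
            assert r.p_adjusted <= 1.0

    def test_pair_statistic_matches_moment_formula(self):
        """Independent recomputation of the standardized linear statistic."""
        rng = np.random.default_rng(4)
        va, vb = rng.normal(size=6), rng.normal(loc=1.0, size=5)
        v = np.concatenate([va, vb])
        g = np.array(["a"] * 6 + ["b"] * 5)
        res = fp_pairwise(v, g)[0]
        N, na = 11, 6
        ybar = v.mean()
        s2 = np.sum((v - ybar) ** 2) / N
        var = s2 * N / (N - 1) * na * (1 - na / N)
        z = (va.sum() - na * ybar) / np.sqrt(var)
        assert res.statistic == pytest.approx(z, abs=1e-12)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)


class TestBenjaminiHochberg:
    def test_step_up_arithmetic_by_hand(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_hand_case_with_distinct_adjustments(self):
        adj = benjamini_hochberg([0.01, 0.04, 0.9])
        # p_(3)=0.9; p_(2)=min(0.9, 0.04*3/2)=0.06; p_(1)=min(0.06, 0.01*3)=0.03
        assert np.allclose(adj, [0.03, 0.06, 0.9])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=12)
    )
    def test_monotone_and_bounded(self, pvals):
        adj = benjamini_hochberg(pvals)
        order = np.argsort(pvals)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)


class TestVarianceChecks:
    def test_equal_variances_by_construction(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        v = np.concatenate([base, base + 10.0])
        g = np.array(["a"] * 8 + ["b"] * 8)
        res = variance_checks(v, g)
        assert res.homogeneity_p > 0.9

    def test_constant_values(self):
        res = variance_checks([2.0] * 10, ["a"] * 5 + ["b"] * 5)
        assert res.homogeneity_p == 1.0

    def test_bartlett_power_on_unequal_variances(self):
        """N(0,1) vs N(0,9), n=20 each: rejected at 5% nearly always."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            v = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 3, 20)])
            g = np.array(["a"] * 20 + ["b"] * 20)
            stat, p = stats.bartlett(v[:20], v[20:])
            rejections += p < 0.05
        assert rejections / n_rep >= 0.95

    def test_small_group_excluded_with_warning(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        g = ["a", "a", "b", "b", "c"]
        res = variance_checks(v, g)
        assert any("excluded" in w for w in res.warnings)

    def test_heterogeneity_warns_but_computes(self):
        rng = np.random.default_rng(6)
        v = np.concatenate([rng.normal(0, 0.1, 15), rng.uniform(-20, 20, 15)])
        g = np.array(["a"] * 15 + ["b"] * 15)
        res = variance_checks(v, g)
        assert res.homogeneity_p < 0.05
        assert any("caution" in w for w in res.warnings)
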