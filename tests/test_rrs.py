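import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import salarfit as sf
from salarfit.errors import UndefinedRRSError, ValidationError

from conftest import exhaustive_perm_p


class TestUnbiasedMeanLrs:
    def test_identity_at_zero_epsilon(self):
        assert sf.unbiased_mean_lrs(2.0, 100, 90, 50, 0.0) == 2.0

    def test_identity_when_all_assigned(self):
        assert sf.unbiased_mean_lrs(2.0, 100, 100, 50, 0.3) == 2.0

    def test_hand_computed_correction(self):
        # (100 - 90)/50 * 0.05/0.95 = 0.2 * 1/19
        expected = 2.0 - 0.2 * (0.05 / 0.95)
        assert sf.unbiased_mean_lrs(2.0, 100, 90, 50, 0.05) == pytest.approx(
            expected, abs=1e-15
        )
        assert expected == pytest.approx(1.9894736842, abs=1e-9)

    def test_randomised_tuples_match_direct_arithmetic(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            S = int(rng.integers(1, 1000))
            A = int(rng.integers(0, S + 1))
            N = int(rng.integers(1, 500))
            eps = float(rng.uniform(0, 0.5))
            raw = float(rng.uniform(0, 5))
            step_i = S - A
            step_ii = step_i / N
            step_iii = step_ii * eps / (1 - eps)
            assert sf.unbiased_mean_lrs(raw, S, A, N, eps) == pytest.approx(
                raw - step_iii, abs=1e-12
            )

    @given(
        raw=st.floats(0, 10),
        s=st.integers(0, 1000),
        extra=st.integers(0, 100),
        n=st.integers(1, 100),
        eps=st.floats(0, 0.9),
        eps2=st.floats(0, 0.9),
    )
    def test_monotone_in_epsilon_and_unassigned(self, raw, s, extra, n, eps, eps2):
        """Corrected mean is non-increasing in eps and in S - A."""
        a = max(s - extra, 0)
        lo, hi = sorted([eps, eps2])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert sf.unbiased_mean_lrs(raw, s, a, n, hi) <= sf.unbiased_mean_lrs(
                raw, s, a, n, lo
            ) + 1e-12
            if a > 0:
                assert sf.unbiased_mean_lrs(raw, s, a - 1, n, hi) <= sf.unbiased_mean_lrs(
                    raw, s, a, n, hi
                ) + 1e-12

    def test_validation_errors(self):
        with pytest.raises(ValidationError):
            sf.unbiased_mean_lrs(1.0, 10, 5, 0, 0.1)
        with pytest.raises(ValidationError):
            sf.unbiased_mean_lrs(1.0, 10, 5, 5, 1.0)
        with pytest.raises(ValidationError):
            sf.unbiased_mean_lrs(1.0, 5, 10, 5, 0.1)

    def test_negative_result_warns_and_clamps_optionally(self):
        with pytest.warns(UserWarning, match="negative"):
            v = sf.unbiased_mean_lrs(0.01, 1000, 0, 1, 0.5)
        assert v < 0
        with pytest.warns(UserWarning):
            assert sf.unbiased_mean_lrs(0.01, 1000, 0, 1, 0.5, clamp=True) == 0.0


class TestCohortRrs:
    def test_ratio_arithmetic(self):
        assert sf.cohort_rrs(1.5, 1.5) == 1.0
        assert sf.cohort_rrs(0.36, 1.0) == pytest.approx(0.36)
        assert sf.cohort_rrs(0.0, 2.0) == 0.0

    def test_nonpositive_wild_mean_raises_with_cohort(self):
        with pytest.raises(UndefinedRRSError, match="1985"):
            sf.cohort_rrs(0.5, 0.0, cohort=1985)


class TestPermutationTest:
    def test_identical_constant_groups_weak_p_one(self):
        with pytest.warns(UserWarning, match="constant"):
            res = sf.permutation_test([2, 2], [2, 2], n_perm=100, seed=0)
        assert res.observed_diff == 0.0
        assert res.p == 1.0

    def test_exhaustive_small_example(self):
        strict = sf.permutation_test([0, 0], [5, 5], tie_rule="strict", exact=True)
        weak = sf.permutation_test([0, 0], [5, 5], tie_rule="weak", exact=True)
        assert strict.n_perm == 6  # C(4, 2) label arrangements
        assert strict.p == 0.0
        assert weak.p == pytest.approx(1 / 6)

    @pytest.mark.parametrize(
        "captive,wild",
        [([0, 1, 3], [2, 4, 4, 5]), ([1, 1, 2, 2], [0, 3, 5]), ([0, 0, 0], [0, 1, 2])],
    )
    def test_exact_mode_matches_independent_enumeration(self, captive, wild):
        for rule in ("strict", "weak"):
            res = sf.permutation_test(captive, wild, tie_rule=rule, exact=True)
            assert res.p == pytest.approx(exhaustive_perm_p(captive, wild, rule))

    def test_monte_carlo_close_to_exact(self):
        captive, wild = [0, 2, 5, 1], [3, 4, 6, 7, 2]
        p_exact = exhaustive_perm_p(captive, wild, "strict")
        res = sf.permutation_test(
            captive, wild, n_perm=20_000, tie_rule="strict", seed=7
        )
        sd = math.sqrt(p_exact * (1 - p_exact) / res.n_perm)
        assert abs(res.p - p_exact) < 3 * sd + 1e-12

    def test_weak_rule_never_zero(self):
        res = sf.permutation_test([0, 0, 0], [9, 9, 9], n_perm=500, seed=1)
        assert res.p > 0

    def test_empty_group_raises(self):
        with pytest.raises(ValidationError):
            sf.permutation_test([], [1, 2], n_perm=10)


class TestFisherCombined:
    def test_df_is_twice_k(self):
        res = sf.fisher_combined([0.5] * 6)
        assert res.df == 12

    def test_closed_form_chi2(self):
        res = sf.fisher_combined([0.5] * 6)
        assert res.chi2 == pytest.approx(-12 * math.log(0.5), rel=1e-12)
        assert res.p == pytest.approx(stats.chi2.sf(res.chi2, 12), rel=1e-12)

    def test_p_equal_one_contributes_nothing(self):
        base = sf.fisher_combined([0.1, 0.2])
        plus = sf.fisher_combined([0.1, 0.2, 1.0])
        assert plus.chi2 == pytest.approx(base.chi2)

    def test_zero_substitution_uses_permutation_floor(self):
        res = sf.fisher_combined([0.0, 0.5], n_perm=999)
        assert res.substitutions == [{"index": 0, "substituted_p": 1 / 1000}]
        assert res.chi2 == pytest.approx(-2 * (math.log(1 / 1000) + math.log(0.5)))

    def test_zero_substitution_takes_more_conservative(self):
        res = sf.fisher_combined([0.0], n_perm=999, alternatives=[0.01])
        assert res.substitutions[0]["substituted_p"] == 0.01  # max(1/1000, 0.01)

    def test_errors(self):
        with pytest.raises(ValidationError):
            sf.fisher_combined([])
        with pytest.raises(ValidationError):
            sf.fisher_combined([1.2])
        with pytest.raises(ValidationError):
            sf.fisher_combined([0.0, 0.5], zero_policy="error")

    def test_mean_chi2_of_uniform_ps_is_2k(self):
        rng = np.random.default_rng(0)
        k = 6
        chis = [
            sf.fisher_combined(rng.uniform(size=k)).chi2 for _ in range(400)
        ]
        # chi2 with 2k df has mean 2k and variance 4k
        assert np.mean(chis) == pytest.approx(2 * k, abs=3 * math.sqrt(4 * k / 400))


class TestOverallRrs:
    def test_invariance_when_all_equal(self):
        assert sf.overall_rrs([0.7, 0.7, 0.7], [1, 5, 2]) == pytest.approx(0.7)

    def test_closed_form_geometric_mean(self):
        assert sf.overall_rrs([0.25, 1.0], [1, 1]) == pytest.approx(0.5)

    def test_single_cohort(self):
        assert sf.overall_rrs([0.36], [3.0]) == pytest.approx(0.36)

    def test_nonpositive_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="non-positive"):
            v = sf.overall_rrs([0.0, 0.5], [1, 1])
        assert v == pytest.approx(0.5)
        with pytest.raises(ValidationError):
            with pytest.warns(UserWarning):
                sf.overall_rrs([0.0, 0.0], [1, 1])

    @given(
        r=st.lists(st.floats(0.01, 10), min_size=2, max_size=8),
        w=st.lists(st.floats(0.1, 10), min_size=2, max_size=8),
    )
    def test_bounded_by_min_and_max(self, r, w):
        n = min(len(r), len(w))
        v = sf.overall_rrs(r[:n], w[:n])
        assert min(r[:n]) - 1e-9 <= v <= max(r[:n]) + 1e-9


class TestZeroLrsProportionTest:
    def test_equal_proportions_uncorrected(self):
        chi2, p = sf.zero_lrs_proportion_test(30, 100, 30, 100, continuity=False)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_matches_2x2_chi_squared_formula(self):
        a, b = 90, 10  # captive: zero / nonzero
        c, d = 50, 50  # wild
        n = a + b + c + d
        hand_chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, p = sf.zero_lrs_proportion_test(90, 100, 50, 100, continuity=False)
        assert chi2 == pytest.approx(hand_chi2, rel=1e-12)
        assert p < 0.001  # captive-higher direction

    def test_direction_symmetry(self):
        _, p1 = sf.zero_lrs_proportion_test(90, 100, 50, 100, continuity=False)
        _, p2 = sf.zero_lrs_proportion_test(50, 100, 90, 100, continuity=False)
        assert p1 + p2 == pytest.approx(1.0)

    def test_zero_totals_error(self):
        with pytest.raises(ValidationError):
            sf.zero_lrs_proportion_test(0, 0, 5, 10)


class TestZeroExcludedRrs:
    def test_ratio_after_filtering(self):
        rrs, p = sf.zero_excluded_rrs([0, 2], [0, 2], n_perm=100, seed=0)
        assert rrs == pytest.approx(1.0)

    def test_all_zero_group_raises(self):
        with pytest.raises(ValidationError):
            sf.zero_excluded_rrs([0, 0], [1, 2], n_perm=10)

    def test_separates_zero_inflation_from_conditional_fitness(self):
        # equal positive-part means but heavier zero inflation in captives:
        # zero-excluded RRS ~ 1 while the all-records RRS is well below 1
        rng = np.random.default_rng(3)
        pos = lambda n: 1 + rng.poisson(1.5, n)
        captive = np.where(rng.random(4000) < 0.8, 0, pos(4000))
        wild = np.where(rng.random(4000) < 0.4, 0, pos(4000))
        zrrs, _ = sf.zero_excluded_rrs(captive, wild, n_perm=200, seed=1)
        all_rrs = captive.mean() / wild.mean()
        assert zrrs == pytest.approx(1.0, abs=0.1)
        assert all_rrs < 0.5


class TestMixedPopulationReduction:
    def test_no_reduction_cases(self):
        assert sf.mixed_population_reduction([10, 20], [1.0, 1.0], [30, 40]) == 0.0
        assert sf.mixed_population_reduction([0, 0], [0.3, 0.9], [30, 40]) == 0.0

    def test_direct_arithmetic(self):
        # 100 * (1 - (50*0.36 + 50) / 100) = 32%
        assert sf.mixed_population_reduction([50], [0.36], [50]) == pytest.approx(32.0)

    def test_weighted_average_bounds_without_wild(self):
        r = [0.2, 0.5, 0.9]
        v = sf.mixed_population_reduction([10, 20, 30], r, [0, 0, 0])
        assert 100 * (1 - max(r)) - 1e-9 <= v <= 100 * (1 - min(r)) + 1e-9

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            sf.mixed_population_reduction([1, 2], [0.5], [1, 2])


class TestCohortFitnessTable:
    def test_table_shape_and_internal_consistency(self, default_bundle):
        cfg, bundle, fish, lrs = default_bundle
        tab = sf.cohort_fitness_table(
            fish, lrs, bundle.parentage, cfg.years, n_perm=500, seed=5
        )
        assert list(tab["cohort"]) == list(cfg.years)
        np.testing.assert_allclose(
            tab["rrs"], tab["corrected_mean_captive"] / tab["corrected_mean_wild"]
        )
        assert ((tab["perm_p"] > 0) & (tab["perm_p"] <= 1)).all()
        # correction only lowers means (eps > 0, unassigned offspring exist)
        assert (tab["corrected_mean_captive"] <= tab["raw_mean_captive"]).all()
        assert (tab["corrected_mean_wild"] <= tab["raw_mean_wild"]).all()

    def test_epsilon_zero_equals_raw(self, default_bundle):
        cfg, bundle, fish, lrs = default_bundle
        tab = sf.cohort_fitness_table(
            fish, lrs, bundle.parentage, cfg.years, epsilon=0.0, n_perm=10, seed=0
        )
        np.testing.assert_allclose(tab["corrected_mean_wild"], tab["raw_mean_wild"])

    def test_sex_specific_subset(self, default_bundle):
        cfg, bundle, fish, lrs = default_bundle
        full = sf.cohort_fitness_table(
            fish, lrs, bundle.parentage, cfg.years, n_perm=10, seed=0
        )
        female = sf.cohort_fitness_table(
            fish, lrs, bundle.parentage, cfg.years, n_perm=10, seed=0, sex="F"
        )
        male = sf.cohort_fitness_table(
            fish, lrs, bundle.parentage, cfg.years, n_perm=10, seed=0, sex="M"
        )
        merged = full.merge(female, on="cohort", suffixes=("", "_f")).merge(
            male.rename(columns=lambda c: c + "_m" if c != "cohort" else c), on="cohort"
        )
        assert (merged["n_captive_f"] + merged["n_captive_m"] <= merged["n_captive"]).all()
        assert (merged["n_captive_f"] < merged["n_captive"]).all()
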