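"""Group comparisons, dichotomization, and survival statistics, checked
against enumeration oracles and external reference implementations."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emtridge.clinical_assoc import (
    dichotomize_median,
    km_estimate,
    logrank_test,
    mandard_association,
    mann_whitney_u,
    spearman,
    spearman_rho,
    welch_t,
)
from emtridge.exceptions import ValidationError


class TestMannWhitney:
    def test_tiny_exact_enumeration(self):
        """a=(1,2), b=(3,4): U_a = 0; exact two-sided p = 2/6."""
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "mann-whitney-exact"

    def test_identical_multisets(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n_a*n_b/2
        assert res.p_value == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        a=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        b=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
    )
    def test_u_identity(self, a, b):
        ua = mann_whitney_u(a, b).statistic
        ub = mann_whitney_u(b, a).statistic
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_exact_matches_scipy(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(15):
            a = rng.permutation(20)[:5].astype(float)
            b = rng.permutation(np.arange(20, 40))[:6].astype(float)
            for alt in ("two-sided", "greater", "less"):
                ours = mann_whitney_u(a, b, alternative=alt)
                ref = mannwhitneyu(a, b, alternative=alt, method="exact")
                assert ours.statistic == pytest.approx(ref.statistic)
                assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_close_to_scipy(self, rng):
        from scipy.stats import mannwhitneyu

        a = rng.normal(size=25)
        b = rng.normal(0.5, 1.0, size=30)
        ours = mann_whitney_u(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


class TestWelch:
    def test_hand_formula_oracle(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=14)
        res = welch_t(a, b)
        sa, sb = a.var(ddof=1) / 9, b.var(ddof=1) / 14
        t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / 8 + sb**2 / 13)
        from scipy.stats import t as tdist

        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p_value == pytest.approx(2 * tdist.sf(abs(t), df), abs=1e-12)

    def test_matches_scipy(self, rng):
        from scipy.stats import ttest_ind

        a = rng.normal(size=8)
        b = rng.normal(1.0, 2.0, size=12)
        ours = welch_t(a, b, alternative="greater")
        ref = ttest_ind(a, b, equal_var=False, alternative="greater")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_strong_separation(self, rng):
        a = rng.normal(size=10) + 100.0
        b = rng.normal(size=10)
        assert welch_t(a, b, alternative="greater").p_value < 1e-6

    def test_identical_groups(self):
        res = welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            welch_t([2.0, 2.0], [2.0, 2.0])


class TestSpearman:
    def test_monotone_bounds(self):
        x = [1.0, 3, 4, 7, 9]
        assert spearman(x, [2.0, 4, 5, 8, 11]).statistic == pytest.approx(1.0)
        assert spearman(x, [-1.0, -3, -4, -7, -9]).statistic == pytest.approx(-1.0)

    def test_exact_p_matches_independent_permutation_oracle(self, rng):
        """n=5: compare against a literal loop over all 120 permutations."""
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        res = spearman(x, y)
        obs = spearman_rho(x, y)
        count = 0
        for perm in itertools.permutations(y):
            if abs(spearman_rho(x, list(perm))) >= abs(obs) - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / 120)
        assert res.method == "spearman-exact"

    def test_approximation_close_to_scipy_large_n(self, rng):
        from scipy.stats import spearmanr

        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        ours = spearman(x, y)
        ref = spearmanr(x, y)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-2)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            spearman([1.0, 2, 3, 4], [1.0, 2, 3])


class TestDichotomize:
    def test_even_split(self):
        assert dichotomize_median([1, 2, 3, 4]).tolist() == [
            "low", "low", "high", "high",
        ]

    def test_ties_go_low(self):
        assert dichotomize_median([1, 2, 2, 3]).tolist() == [
            "low", "low", "low", "high",
        ]

    def test_degenerate_all_equal_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            labels = dichotomize_median([5.0, 5.0, 5.0])
        assert set(labels) == {"low"}
        assert any("degenerate" in r.message for r in caplog.records)

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            dichotomize_median([1.0])


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [False, False, False])
        assert len(curve.event_times) == 0
        assert curve.survival_at(99.0) == 1.0

    def test_two_events_closed_form(self):
        curve = km_estimate([1.0, 2.0], [True, True])
        assert np.allclose(curve.survival, [0.5, 0.0])

    def test_hand_computed_mixed_censoring(self):
        """times (1, 2+, 3, 4, 5+, 6), events at 1, 3, 4, 6.

        Product-limit by hand: S(1)=5/6, S(3)=5/6 * 3/4 = 5/8,
        S(4)=5/8 * 2/3 = 5/12, S(6)=0.
        """
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        e = [True, False, True, True, False, True]
        curve = km_estimate(t, e)
        assert curve.event_times.tolist() == [1.0, 3.0, 4.0, 6.0]
        assert np.allclose(curve.survival, [5 / 6, 5 / 8, 5 / 12, 0.0])
        assert curve.at_risk.tolist() == [6, 4, 3, 1]

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10.0, size=30)
        curve = km_estimate(t, np.ones(30, bool))
        for q in (2.0, 5.0, 15.0):
            assert curve.survival_at(q) == pytest.approx(np.mean(t > q))

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10.0, size=40)
        e = rng.uniform(size=40) < 0.7
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for ut, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(ut).iloc[0]), abs=1e-10
            )

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([-1.0, 2.0], [True, True])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2, 3, 4, 1.0, 2, 3, 4]
        e = [True] * 8
        g = ["a"] * 4 + ["b"] * 4
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_significant(self, rng):
        t = np.r_[rng.uniform(0.1, 1.0, 10), rng.uniform(50.0, 60.0, 10)]
        e = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        g = ["early"] * 10 + ["late"] * 10
        assert logrank_test(t, e, g).p_value < 0.01

    def test_label_swap_invariance(self, rng):
        t = rng.exponential(5.0, size=30)
        e = rng.uniform(size=30) < 0.8
        g = np.array(["x"] * 15 + ["y"] * 15)
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, np.where(g == "x", "y", "x"))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        t = rng.exponential(5.0, size=50)
        e = rng.uniform(size=50) < 0.7
        g = np.array(["x"] * 25 + ["y"] * 25)
        ours = logrank_test(t, e, g)
        ref = ll_logrank(t[g == "x"], t[g == "y"], e[g == "x"], e[g == "y"])
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1.0, 2.0], [True, True], ["a", "a"])


class TestMandardAssociation:
    def test_perfect_separation_hits_enumeration_minimum(self):
        scores = np.arange(12, dtype=float)  # strictly ordered by category
        cats = np.repeat([1, 2, 3, 4], 3)
        results = mandard_association(scores, cats)
        assert len(results) == 6  # all pairs of 4 populated categories
        for r in results:
            # exact minimum two-sided p for 3 vs 3 with no ties: 2/C(6,3)
            assert r.p_value == pytest.approx(2 / 20)

    def test_missing_categories_excluded_pairwise(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0, 9.0])
        cats = np.array([1, 1, 2, 2, np.nan])
        results = mandard_association(scores, cats)
        assert len(results) == 1
        assert results[0].n_per_group == (2, 2)

    def test_single_category_rejected(self):
        with pytest.raises(ValidationError):
            mandard_association(np.ones(4), np.array([2, 2, 2, 2]))
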