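"""Chapman estimation, stratified totals, bootstrap CIs and incidence."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from recapture.estimators import (
    CaptureCounts,
    chapman_estimate,
    incidence,
    monte_carlo_ci,
    round_half_away,
    stratified_estimate,
)

# (d1, d2, m) -> published rounded estimate
PUBLISHED_POINTS = [
    ((97, 143, 36), 380),
    ((73, 124, 31), 288),
    ((21, 17, 5), 65),
    ((3, 2, 0), 11),
    ((44, 77, 18), 184),
    ((27, 18, 4), 105),
    ((62, 115, 28), 251),
    ((80, 119, 33), 285),
    ((17, 24, 3), 112),
]


class TestChapman:
    @pytest.mark.parametrize("counts,expected", PUBLISHED_POINTS)
    def test_published_point_estimates(self, counts, expected):
        assert chapman_estimate(CaptureCounts(*counts)).rounded == expected

    def test_pooled_wald_interval(self):
        est = chapman_estimate(CaptureCounts(97, 143, 36))
        assert est.ci_rounded == (298, 463)

    def test_complete_overlap_has_zero_variance(self):
        est = chapman_estimate(CaptureCounts(5, 5, 5))
        assert est.n_hat == 5 and est.variance == 0
        assert est.ci_low == est.ci_high == 5

    def test_subset_case_recovers_larger_source(self):
        # if every police record is also in the hospital file, n_hat = d1
        for d1 in (10, 50, 200):
            est = chapman_estimate(CaptureCounts(d1, 7, 7))
            assert est.n_hat == pytest.approx(d1)

    def test_strictly_decreasing_in_overlap(self):
        values = [chapman_estimate(CaptureCounts(40, 60, m)).n_hat for m in range(0, 41)]
        assert all(a > b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("counts", [(-1, 5, 0), (5, -1, 0), (5, 5, 6), (3, 2, 3)])
    def test_invalid_counts_rejected(self, counts):
        with pytest.raises(ValueError):
            CaptureCounts(*counts)

    @given(
        st.integers(0, 500),
        st.integers(0, 500),
        st.integers(0, 500),
    )
    @settings(max_examples=200, derandomize=True)
    def test_estimate_invariants(self, d1, d2, m):
        m = min(m, d1, d2)
        est = chapman_estimate(CaptureCounts(d1, d2, m))
        assert est.variance >= 0
        assert est.ci_low <= est.n_hat <= est.ci_high
        assert est.n_hat >= d1 + d2 - m - 1  # never below the observed count - 1


class TestExpectationOracle:
    """The estimator's expectation under independent captures, two independent routes."""

    @pytest.mark.parametrize("n,p1,p2", [(5, 0.6, 0.3), (7, 0.4, 0.5)])
    def test_brute_force_enumeration_matches_multinomial_sum(self, n, p1, p2):
        # route 1: enumerate all 4^n per-individual capture outcomes and apply
        # the implementation to each
        states = [(True, True), (True, False), (False, True), (False, False)]
        probs = {
            (True, True): p1 * p2,
            (True, False): p1 * (1 - p2),
            (False, True): (1 - p1) * p2,
            (False, False): (1 - p1) * (1 - p2),
        }
        expect_brute = 0.0
        for outcome in itertools.product(states, repeat=n):
            pr = math.prod(probs[s] for s in outcome)
            d1 = sum(s[0] for s in outcome)
            d2 = sum(s[1] for s in outcome)
            m = sum(s[0] and s[1] for s in outcome)
            expect_brute += pr * chapman_estimate(CaptureCounts(d1, d2, m)).n_hat

        # route 2: closed-form sum over multinomial cell counts with the
        # estimator formula written out independently
        expect_direct = 0.0
        for n11 in range(n + 1):
            for n10 in range(n + 1 - n11):
                for n01 in range(n + 1 - n11 - n10):
                    n00 = n - n11 - n10 - n01
                    pr = (
                        math.comb(n, n11)
                        * math.comb(n - n11, n10)
                        * math.comb(n - n11 - n10, n01)
                        * probs[(True, True)] ** n11
                        * probs[(True, False)] ** n10
                        * probs[(False, True)] ** n01
                        * probs[(False, False)] ** n00
                    )
                    d1, d2, m = n11 + n10, n11 + n01, n11
                    expect_direct += pr * ((d1 + 1) * (d2 + 1) / (m + 1) - 1)
        assert expect_brute == pytest.approx(expect_direct, abs=1e-9)
        # Chapman's small-sample bias is tiny even at these n
        assert expect_brute == pytest.approx(n, rel=0.15)


class TestStratified:
    def test_gender_total_sums_unrounded_estimates(self):
        strata = [
            ("male", CaptureCounts(73, 124, 31)),
            ("female", CaptureCounts(21, 17, 5)),
            ("missing", CaptureCounts(3, 2, 0)),
        ]
        result = stratified_estimate(strata, factor="gender", mc_reps=1000, seed=0)
        assert result.total.rounded == 364
        assert [e.rounded for e in result.estimates] == [288, 65, 11]

    def test_vehicles_total_requires_unrounded_summation(self):
        # 284.88 + 111.50 = 396.38 -> 396; rounding each stratum first gives 397
        strata = [
            ("0-1", CaptureCounts(80, 119, 33)),
            (">=2", CaptureCounts(17, 24, 3)),
        ]
        result = stratified_estimate(strata, mc_reps=1000, seed=0)
        assert result.total.rounded == 396
        assert sum(e.rounded for e in result.estimates) == 397

    def test_single_stratum_equals_pooled(self):
        pooled = chapman_estimate(CaptureCounts(97, 143, 36))
        result = stratified_estimate([("all", CaptureCounts(97, 143, 36))], mc_reps=500, seed=0)
        assert result.total.n_hat == pooled.n_hat

    def test_pooled_counts_recovered(self):
        strata = [("a", CaptureCounts(10, 20, 5)), ("b", CaptureCounts(7, 3, 2))]
        result = stratified_estimate(strata, mc_reps=100, seed=0)
        assert result.pooled_counts == CaptureCounts(17, 23, 7)

    def test_empty_strata_rejected(self):
        with pytest.raises(ValueError):
            stratified_estimate([])


class TestMonteCarloCI:
    def test_large_overlap_stratum_agrees_with_wald(self):
        analytic = chapman_estimate(CaptureCounts(73, 124, 31))
        per, _ = monte_carlo_ci([("male", CaptureCounts(73, 124, 31))], reps=10_000, seed=0)
        lo, hi = per["male"]
        assert lo == pytest.approx(analytic.ci_low, abs=6)
        assert hi == pytest.approx(analytic.ci_high, abs=6)

    def test_subset_stratum_degenerates(self):
        # every hospital record also in police data: no estimation uncertainty
        per, _ = monte_carlo_ci([("motorcyclist", CaptureCounts(2, 1, 1))], reps=5000, seed=0)
        assert per["motorcyclist"] == (2.0, 2.0)

    def test_identical_sources_degenerate_at_point(self):
        per, _ = monte_carlo_ci([("x", CaptureCounts(5, 5, 5))], reps=2000, seed=0)
        lo, hi = per["x"]
        assert lo == pytest.approx(5, abs=1e-9) and hi == pytest.approx(5, abs=1e-9)

    def test_deterministic_under_fixed_seed(self):
        strata = [("a", CaptureCounts(30, 40, 10))]
        assert monte_carlo_ci(strata, 2000, seed=7) == monte_carlo_ci(strata, 2000, seed=7)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_ci([("void", CaptureCounts(0, 0, 0))], reps=100, seed=0)


class TestIncidence:
    POPULATION = 1_898_000

    def test_pooled_estimate_scale(self):
        est = chapman_estimate(CaptureCounts(97, 143, 36))
        inc = incidence(est, self.POPULATION)
        assert inc.rounded() == (0.200, 0.157, 0.244)

    def test_raw_source_counts(self):
        # a raw count is a degenerate estimate with zero width
        for count, expected in ((143, 0.075), (97, 0.051)):
            est = chapman_estimate(CaptureCounts(count, count, count))
            assert incidence(est, self.POPULATION).rounded()[0] == expected

    def test_zero_estimate_gives_zero_incidence(self):
        est = chapman_estimate(CaptureCounts(0, 0, 0))
        assert incidence(est, self.POPULATION).deaths_per_1000py == 0

    def test_non_positive_population_rejected(self):
        est = chapman_estimate(CaptureCounts(5, 5, 2))
        with pytest.raises(ValueError):
            incidence(est, 0)


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(6.5, 7), (111.5, 112), (380.405, 380), (-2.5, -3), (0.49, 0), (2.0, 2)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value) == expected
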