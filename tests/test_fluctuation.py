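"""Rate estimators and deletable-window normalization."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deletometer import (
    DeletableWindow,
    FluctuationError,
    FluctuationExperiment,
    RateEstimate,
    SimulationConfig,
    estimate_rate_median,
    estimate_rate_p0,
    estimate_window,
    fold_range,
    normalize_rate,
    simulate_fluctuation_cultures,
    solve_median_equation,
)

D = 1e9  # divisions for a 1e6 -> ~1e9 culture, plating fraction 1


def _exp(counts, divisions=D):
    return FluctuationExperiment(counts=list(counts), N0=1.0,
                                 Nt=divisions + 1.0)


class TestP0Method:
    def test_all_zero_counts_give_zero_rate_with_upper_bound(self):
        est = estimate_rate_p0(_exp([0] * 9))
        assert est.mu == 0.0
        assert est.ci_mu[0] == 0.0 and est.ci_mu[1] > 0.0

    def test_five_zeros_of_nine_closed_form(self):
        est = estimate_rate_p0(_exp([0, 0, 0, 0, 0, 3, 1, 7, 2]))
        assert est.m == pytest.approx(-math.log(5 / 9), rel=1e-12)
        assert est.mu == pytest.approx(0.587787 / D, rel=1e-4)
        assert est.ci_mu[0] < est.mu < est.ci_mu[1]

    def test_no_zero_culture_is_inapplicable(self):
        with pytest.raises(FluctuationError, match="P0 method inapplicable"):
            estimate_rate_p0(_exp([1, 2, 3]))

    def test_plating_fraction_scales_divisor(self):
        full = estimate_rate_p0(_exp([0, 0, 1, 5]))
        half = estimate_rate_p0(
            FluctuationExperiment(counts=[0, 0, 1, 5], N0=1.0, Nt=D + 1.0,
                                  plating_fraction=0.5)
        )
        assert half.mu == pytest.approx(2 * full.mu)

    def test_median_rate_recovery_at_m_of_two(self):
        # m ~ 2 expected mutations per culture; over 500 assays the median
        # P0 estimate should land within 25% of the true rate
        mu_true = 2e-9
        cfg = SimulationConfig(N0=1e6, Nt=1e9, mu_true=mu_true, n_cultures=9)
        mus = []
        for seed in range(500):
            exp = simulate_fluctuation_cultures(cfg, seed=seed)
            try:
                mus.append(estimate_rate_p0(exp).mu)
            except FluctuationError:
                continue
        assert len(mus) > 300
        assert np.median(mus) == pytest.approx(mu_true, rel=0.25)


class TestMedianMethod:
    def test_root_for_median_four_matches_frozen_bisection_value(self):
        # frozen from an independent 200-step bisection of r/m - ln m = 1.24
        assert solve_median_equation(4) == pytest.approx(2.0454099209270113,
                                                         rel=1e-9)

    def test_fixed_point_at_m_equal_one(self):
        # r = 1.24 satisfies r/m - ln m = 1.24 exactly at m = 1
        assert solve_median_equation(1.24) == pytest.approx(1.0, rel=1e-9)

    def test_zero_median_redirects_to_p0(self):
        with pytest.raises(FluctuationError, match="P0"):
            estimate_rate_median(_exp([0, 0, 0, 0, 1]))

    def test_even_length_uses_lower_middle_order_statistic(self):
        # sorted [1, 2, 5, 9]: lower middle is 2
        est = estimate_rate_median(_exp([9, 2, 5, 1]))
        assert est.m == pytest.approx(solve_median_equation(2))

    def test_estimate_and_uncertainty(self):
        est = estimate_rate_median(_exp([4, 0, 12, 3, 4, 7, 1, 30, 4]))
        assert est.mu == pytest.approx(2.0454099209270113 / D, rel=1e-6)
        assert est.se_mu > 0
        assert est.ci_mu[0] <= est.mu <= est.ci_mu[1]


class TestOrderInvariance:
    @pytest.mark.parametrize("method", [estimate_rate_p0, estimate_rate_median])
    def test_estimates_do_not_depend_on_count_order(self, method):
        counts = [0, 4, 1, 22, 0, 3, 9, 2, 5]
        shuffled = counts.copy()
        random.Random(7).shuffle(shuffled)
        a, b = method(_exp(counts)), method(_exp(shuffled))
        assert (a.m, a.mu) == (b.m, b.mu)


class TestDeletableWindow:
    def test_single_observation_closed_forms(self):
        w = estimate_window([10.0], [10.0])
        assert w.L1_est == pytest.approx(20.0)
        assert w.L1_hi == pytest.approx(200.0)

    def test_large_k_limit_converges_to_observed_maximum(self):
        w = DeletableWindow(M1=10.0, M2=7.0, k=10**6)
        assert w.L1_est == pytest.approx(10.0, rel=1e-5)
        assert w.L1_hi == pytest.approx(10.0, rel=1e-4)
        assert w.L2_est == pytest.approx(7.0, rel=1e-5)

    def test_upper_bound_covers_true_extent_95_percent(self):
        # true extent 50 kbp, k = 5 observations per replicate
        rng = np.random.default_rng(42)
        k, reps, true_l = 5, 10_000, 50.0
        maxima = rng.uniform(0, true_l, size=(reps, k)).max(axis=1)
        l_hi = maxima / 0.05 ** (1.0 / k)
        coverage = np.mean(l_hi >= true_l)
        assert abs(coverage - 0.95) < 3 * math.sqrt(0.95 * 0.05 / reps)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            estimate_window([], [1.0])
        with pytest.raises(ValueError):
            estimate_window([1.0, -2.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="same deletions"):
            estimate_window([1.0], [1.0, 2.0])


class TestNormalization:
    def test_per_kbp_rate_is_simple_division(self):
        rate = RateEstimate(m=2.0, mu=2e-8, method="p0", se_mu=0.0,
                            ci_mu=(0.0, 0.0))
        norm = normalize_rate(rate, DeletableWindow(M1=10, M2=10, k=5), 20.0)
        assert norm.mu_per_kbp == pytest.approx(1e-9)

    def test_degenerate_window_collapses_best_onto_upper(self):
        rate = RateEstimate(m=1.0, mu=1e-8, method="p0", se_mu=0.0,
                            ci_mu=(0.0, 0.0))
        w = DeletableWindow(M1=10.0, M2=10.0, k=10**9)
        norm = normalize_rate(rate, w, 20.0)
        assert norm.mu_intrinsic_best == pytest.approx(norm.mu_intrinsic_hi,
                                                       rel=1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(
        mu=st.floats(1e-12, 1e-7),
        m1=st.floats(0.1, 60.0),
        m2=st.floats(0.1, 60.0),
        k=st.integers(1, 30),
    )
    def test_bound_ordering_lo_le_best_le_hi(self, mu, m1, m2, k):
        rate = RateEstimate(m=1.0, mu=mu, method="median", se_mu=0.0,
                            ci_mu=(0.0, 0.0))
        norm = normalize_rate(rate, DeletableWindow(M1=m1, M2=m2, k=k),
                              max(m1, m2))
        assert norm.mu_intrinsic_lo <= norm.mu_intrinsic_best
        assert norm.mu_intrinsic_best <= norm.mu_intrinsic_hi

    def test_zero_window_dimension_raises(self):
        rate = RateEstimate(m=1.0, mu=1e-8, method="p0", se_mu=0.0,
                            ci_mu=(0.0, 0.0))
        with pytest.raises(ValueError):
            normalize_rate(rate, DeletableWindow(M1=0.0, M2=10.0, k=3), 10.0)


class TestFoldRange:
    def _norm(self, per_kbp):
        return [
            type("N", (), {"mu_per_kbp": v, "mu_raw": v})() for v in per_kbp
        ]

    def test_identical_rates_give_unity(self):
        assert fold_range(self._norm([3e-10] * 4)) == 1.0

    def test_two_decades_give_hundredfold(self):
        assert fold_range(self._norm([1e-11, 1e-9])) == pytest.approx(100.0)

    def test_eleven_region_synthetic_ratio_exact(self):
        values = np.geomspace(0.5e-11, 1.25e-9, 11)
        assert fold_range(self._norm(values)) == pytest.approx(250.0, rel=1e-9)
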