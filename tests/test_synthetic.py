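"""Generator correctness against independent statistical oracles."""

import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from deletometer import (
    DeletionEvent,
    SimulationConfig,
    find_junction_homology,
    plant_junction,
    random_genome,
    simulate_competition,
    simulate_deletion_events,
    simulate_fluctuation_cultures,
    simulate_growth_curve,
)
from deletometer.fitness import fit_growth_rate, fit_selection_coefficient


class TestFluctuationCultures:
    def test_zero_mutation_rate_yields_all_zero_counts(self):
        cfg = SimulationConfig(seed=11, mu_true=0.0)
        exp = simulate_fluctuation_cultures(cfg)
        assert exp.counts == [0] * cfg.n_cultures

    def test_high_rate_assays_always_contain_mutants(self):
        # m ~ 22 mutations/culture: P(all nine cultures zero) ~ exp(-9*22)
        cfg = SimulationConfig(N0=1e6, Nt=1e9, mu_true=2.2e-8,
                               plating_fraction=1.0)
        for seed in range(50):
            exp = simulate_fluctuation_cultures(cfg, seed=seed)
            assert max(exp.counts) >= 1

    def test_single_doubling_counts_match_poisson_oracle(self):
        # One doubling from a single cell: every mutant is a singleton, so
        # the count per culture is exactly Poisson(mu).
        mu = 0.5
        cfg = SimulationConfig(seed=5, N0=1, Nt=2, mu_true=mu,
                               n_cultures=100_000, plating_fraction=1.0)
        counts = np.array(simulate_fluctuation_cultures(cfg).counts)
        n = len(counts)
        for k in (0, 1, 2, 3):
            p = math.exp(-mu) * mu**k / math.factorial(k)
            emp = np.mean(counts == k)
            assert abs(emp - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_zero_count_fraction_matches_poisson_identity(self):
        # -ln(fraction of zero cultures) -> mu (Nt - N0): the identity the
        # P0 estimator inverts.
        cfg = SimulationConfig(seed=8, N0=1e6, Nt=1e9, n_cultures=30_000,
                               mu_true=1.0 / (1e9 - 1e6),
                               plating_fraction=1.0)
        counts = np.array(simulate_fluctuation_cultures(cfg).counts)
        m_emp = -math.log(np.mean(counts == 0))
        assert abs(m_emp - 1.0) < 0.02

    def test_reproducible_given_seed(self):
        cfg = SimulationConfig(seed=3, mu_true=5e-9)
        a = simulate_fluctuation_cultures(cfg)
        b = simulate_fluctuation_cultures(cfg)
        assert a.counts == b.counts


class TestDeletionEvents:
    def test_sizes_bounded_and_marker_spanned(self):
        cfg = SimulationConfig(seed=2, deletable_left_kbp=10,
                               deletable_right_kbp=10, min_deletion_kbp=2,
                               genome_length_bp=100_000)
        marker = 50_000
        events = simulate_deletion_events(cfg, marker, n_events=1000)
        assert len(events) == 1000
        for ev in events:
            assert 2000 <= ev.size <= 20_000
            assert ev.start <= marker < ev.end

    def test_minimum_equal_to_window_forces_full_window(self):
        cfg = SimulationConfig(seed=2, deletable_left_kbp=10,
                               deletable_right_kbp=10, min_deletion_kbp=20,
                               genome_length_bp=100_000)
        events = simulate_deletion_events(cfg, 50_000, n_events=20)
        for ev in events:
            assert (ev.start, ev.end) == (40_000, 60_000)

    def test_window_too_small_raises(self):
        with pytest.raises(ValueError, match="deletable window"):
            SimulationConfig(deletable_left_kbp=0.5, deletable_right_kbp=0.5,
                             min_deletion_kbp=2)
        # window valid per config but truncated by the genome end
        cfg = SimulationConfig(seed=0, deletable_left_kbp=10,
                               deletable_right_kbp=10, min_deletion_kbp=19,
                               genome_length_bp=100_000)
        with pytest.raises(ValueError, match="truncated"):
            simulate_deletion_events(cfg, marker_position=500)

    def test_size_distribution_matches_independent_rejection_oracle(self):
        cfg = SimulationConfig(seed=9, deletable_left_kbp=10,
                               deletable_right_kbp=10, min_deletion_kbp=2,
                               genome_length_bp=100_000)
        marker = 50_000
        n = 100_000
        sizes = np.array(
            [ev.size for ev in simulate_deletion_events(cfg, marker, n_events=n)]
        )
        # independent scalar rejection sampler, written from the definition
        rng = np.random.default_rng(12345)
        oracle = []
        while len(oracle) < n:
            s = rng.integers(40_000, marker + 1, size=4 * n)
            e = rng.integers(marker, 60_001, size=4 * n)
            ok = (e - s >= 2000) & (e > marker)
            oracle.extend((e[ok] - s[ok]).tolist())
        oracle = np.array(oracle[:n])
        assert ks_2samp(sizes, oracle).statistic < 0.02


class TestPlantJunction:
    @pytest.mark.parametrize("h", [0, 1, 8, 15])
    def test_planted_homology_recovered_exactly(self, h):
        rng = np.random.default_rng(h)
        genome = random_genome(3000, rng)
        ev = DeletionEvent("c", 1000, 2000)
        planted = plant_junction(genome, ev, h, seed=h)
        assert find_junction_homology(planted, ev).homology_bp == h
        assert (
            find_junction_homology(planted, ev, scan_upstream=True).homology_bp
            == h
        )

    def test_recovery_exact_over_100_seeds(self):
        ev = DeletionEvent("c", 700, 1600)
        for seed in range(100):
            genome = random_genome(2500, np.random.default_rng(seed))
            planted = plant_junction(genome, ev, 15, seed=seed)
            assert find_junction_homology(planted, ev).homology_bp == 15

    def test_homology_exceeding_flank_raises(self):
        genome = random_genome(100, np.random.default_rng(0))
        with pytest.raises(ValueError, match="does not fit"):
            plant_junction(genome, DeletionEvent("c", 10, 95), 10)
        with pytest.raises(ValueError, match="does not fit"):
            plant_junction(genome, DeletionEvent("c", 40, 45), 10)


class TestCompetition:
    def test_neutral_log_ratio_is_flat(self):
        cfg = SimulationConfig(seed=21, s_true=0.0, n_cycles=5)
        est = fit_selection_coefficient(simulate_competition(cfg))
        assert abs(est.s) < 3 * est.se_s + 1e-12

    def test_noiseless_slope_is_log_one_plus_s(self):
        cfg = SimulationConfig(seed=0, s_true=0.05, n_cycles=5)
        traj = simulate_competition(cfg, exact_counts=True)
        est = fit_selection_coefficient(traj)
        assert est.s == pytest.approx(math.log(1.05), abs=1e-10)

    def test_mean_recovered_s_within_ten_percent(self):
        cfg0 = SimulationConfig(s_true=0.01, events_per_timepoint=100_000,
                                n_cycles=5)
        shats = [
            fit_selection_coefficient(simulate_competition(cfg0, seed=i)).s
            for i in range(200)
        ]
        assert abs(np.mean(shats) - math.log(1.01)) < 0.1 * 0.01


class TestGrowthCurves:
    def test_noiseless_logistic_recovers_rate_in_exponential_phase(self):
        # deep exponential phase: carrying capacity far above the readings
        cfg = SimulationConfig(seed=0, growth_rate_true=1.2, noise_sd=0.0,
                               carrying_capacity=20.0, duration_h=6.0)
        est = fit_growth_rate(simulate_growth_curve(cfg))
        assert est.rate == pytest.approx(1.2, rel=0.01)

    def test_infinite_capacity_limit_is_pure_exponential(self):
        cfg = SimulationConfig(seed=0, growth_rate_true=1.2, noise_sd=0.0,
                               carrying_capacity=1e9, duration_h=6.0)
        est = fit_growth_rate(simulate_growth_curve(cfg))
        assert est.rate == pytest.approx(1.2, rel=1e-4)
        assert est.r2 > 0.999999

    def test_median_recovered_rate_within_five_percent_under_noise(self):
        cfg0 = SimulationConfig(growth_rate_true=1.2, noise_sd=0.005,
                                carrying_capacity=1.5)
        # fit only readings clear of the blank: below ~4 noise SD above
        # zero, ln(OD) is noise-dominated and the max-slope window fit
        # chases noise instead of growth
        rates = [
            fit_growth_rate(simulate_growth_curve(cfg0, seed=i),
                            detection_floor=0.02).rate
            for i in range(100)
        ]
        assert np.median(rates) == pytest.approx(1.2, rel=0.05)

    def test_detection_floor_applied(self):
        cfg = SimulationConfig(seed=1, noise_sd=0.05, od_initial=0.001,
                               detection_floor=0.01)
        curve = simulate_growth_curve(cfg)
        assert curve.od.min() >= 0.01
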