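"""Analytic Jackson-network law, dwell-time inversion, and the simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from porequeue.queueing import (
    DwellTimeModel,
    JacksonModel,
    NonErgodicError,
    SimulationResult,
    invert_dwell_time,
    occupancy_rate_analytic,
    per_minute,
    queue_probability,
    sensitivity_grid,
    simulate_network,
    snapshot_census,
    state_distribution,
)

LAM = per_minute(4000.0)  # the wild-type cargo flux, per second


class TestAnalyticLaw:
    @pytest.mark.parametrize(
        "flux, n, d, expected",
        [
            (LAM, 110, 0.089, LAM * 0.089 / 110),  # = 0.05394, prints as 5.4%
            (LAM, 110, 0.0, 0.0),
            (LAM, 90, 0.089, LAM * 0.089 / 90),  # = 0.06593
        ],
    )
    def test_occupancy_rate(self, flux, n, d, expected):
        psi = occupancy_rate_analytic(JacksonModel(flux, n, d))
        assert psi == pytest.approx(expected, rel=1e-12)

    def test_fitted_dwell_time_reproduces_measured_occupancy(self):
        """89 ms at 110 NPCs and 4000/min prints as the measured 5.4%."""
        psi = occupancy_rate_analytic(JacksonModel(LAM, 110, 0.089))
        assert round(100 * psi, 1) == 5.4

    def test_psi_recomputes_from_parameters(self):
        m = JacksonModel(2.5, 7, 0.4)
        assert m.psi == 2.5 * 0.4 / 7

    def test_non_ergodic_rejected(self):
        with pytest.raises(NonErgodicError):
            JacksonModel(10.0, 2, 1.0)  # psi = 5

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(flux_lambda=-1.0, n_servers=10, dwell_time=0.1),
            dict(flux_lambda=1.0, n_servers=0, dwell_time=0.1),
            dict(flux_lambda=1.0, n_servers=10, dwell_time=-0.1),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            JacksonModel(**kwargs)


class TestDwellInversion:
    @pytest.mark.parametrize(
        "occupancy, n, expected_ms",
        [
            (0.054, 110, 89.1),  # rounds to the canonical 89 ms
            (0.0, 110, 0.0),
            (0.07, 110, 115.5),
        ],
    )
    def test_examples(self, occupancy, n, expected_ms):
        d = invert_dwell_time(occupancy, n, LAM)
        assert 1000 * d == pytest.approx(expected_ms, abs=0.05)

    def test_canonical_dwell_rounds_to_89_ms(self):
        assert round(1000 * invert_dwell_time(0.054, 110, LAM)) == 89

    def test_errors(self):
        with pytest.raises(NonErgodicError):
            invert_dwell_time(1.0, 110, LAM)
        with pytest.raises(ValueError):
            invert_dwell_time(-0.1, 110, LAM)
        with pytest.raises(ValueError):
            invert_dwell_time(0.05, 0, LAM)
        with pytest.raises(ValueError):
            invert_dwell_time(0.05, 110, 0.0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        flux=st.floats(1e-3, 1e4),
        n=st.integers(1, 10_000),
        d=st.floats(0, 10.0),
    )
    def test_round_trip(self, flux, n, d):
        """invert(occupancy(model)) recovers d to 1e-12 relative."""
        if flux * d / n >= 1:
            return
        m = JacksonModel(flux, n, d)
        d_back = invert_dwell_time(occupancy_rate_analytic(m), n, flux)
        assert d_back == pytest.approx(d, rel=1e-12, abs=1e-15)


class TestStateDistribution:
    def test_psi_zero_is_point_mass(self):
        dist = state_distribution(0.0, k_max=5)
        assert dist.pmf[0] == 1.0
        assert dist.pmf[1:].sum() == 0.0
        assert dist.tail == 0.0

    def test_queue_prediction_at_measured_occupancy(self):
        """At psi = 0.054 only 0.3% of NPCs should have a queue."""
        dist = state_distribution(0.054, k_max=5)
        assert dist.prob_at_least(2) == pytest.approx(0.002916, abs=1e-9)
        assert round(100 * queue_probability(0.054), 1) == 0.3
        assert dist.pmf[1] == pytest.approx(0.054 * 0.946, rel=1e-12)

    @pytest.mark.parametrize("psi", [0.0, 0.054, 0.5, 0.99])
    def test_normalization(self, psi):
        dist = state_distribution(psi, k_max=12)
        assert dist.total_mass() == pytest.approx(1.0, abs=1e-12)

    def test_strictly_decreasing_masses(self):
        dist = state_distribution(0.4, k_max=8)
        assert np.all(np.diff(dist.pmf) < 0)

    @pytest.mark.parametrize("psi", [-0.01, 1.0, 1.5])
    def test_invalid_psi(self, psi):
        with pytest.raises((NonErgodicError, ValueError)):
            state_distribution(psi, 3)
        with pytest.raises((NonErgodicError, ValueError)):
            queue_probability(psi)

    def test_queue_probability_examples(self):
        assert queue_probability(0.0) == 0.0
        assert queue_probability(0.07) == pytest.approx(0.0049, rel=1e-12)


class TestSensitivityGrid:
    def test_single_cell_matches_headline_fit(self):
        grid = sensitivity_grid([110], [0.054], LAM)
        assert grid.dwell_ms.shape == (1, 1)
        assert round(grid.dwell_ms[0, 0]) == 89

    def test_corner_value(self):
        grid = sensitivity_grid([90], [0.04], LAM)
        assert grid.dwell_ms[0, 0] == pytest.approx(54.0, abs=1e-9)

    def test_degenerate_grid_equals_inversion(self):
        grid = sensitivity_grid([97], [0.061], LAM)
        assert grid.dwell_ms[0, 0] == pytest.approx(
            1000 * invert_dwell_time(0.061, 97, LAM), rel=1e-12
        )

    def test_monotone_in_n_and_psi_and_flux(self):
        n = np.arange(90, 131, 10)
        psi = np.linspace(0.04, 0.07, 7)
        grid = sensitivity_grid(n, psi, LAM)
        assert np.all(np.diff(grid.dwell_ms, axis=0) > 0)  # increasing in n
        assert np.all(np.diff(grid.dwell_ms, axis=1) > 0)  # increasing in psi
        faster = sensitivity_grid(n, psi, 2 * LAM)
        assert np.all(faster.dwell_ms < grid.dwell_ms)  # decreasing in lambda

    def test_dwell_range_over_error_domain(self):
        grid = sensitivity_grid([110], [0.054], LAM, domain_polygon=((90, 130), (0.039, 0.069)))
        lo, hi = grid.dwell_range()
        assert lo == pytest.approx(0.039 * 90 / LAM * 1000, rel=1e-12)
        assert hi == pytest.approx(0.069 * 130 / LAM * 1000, rel=1e-12)
        assert lo < 89 < hi

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_grid([], [0.05], LAM)


class TestSimulator:
    def test_zero_service_time_yields_idle_network(self):
        m = JacksonModel(LAM, 110, 0.0)
        res = simulate_network(m, horizon=20.0, warmup=1.0, seed=3)
        assert res.occupied_fraction == 0.0
        assert res.queue_fraction == 0.0
        assert res.state_histogram[0] == pytest.approx(1.0, abs=1e-12)

    def test_bit_reproducible_under_seed(self):
        m = JacksonModel(LAM, 30, 0.1)
        r1 = simulate_network(m, horizon=50.0, warmup=5.0, seed=11)
        r2 = simulate_network(m, horizon=50.0, warmup=5.0, seed=11)
        assert r1.occupied_fraction == r2.occupied_fraction
        assert r1.n_arrivals == r2.n_arrivals
        assert np.array_equal(r1.state_histogram, r2.state_histogram)
        r3 = simulate_network(m, horizon=50.0, warmup=5.0, seed=12)
        assert r3.occupied_fraction != r1.occupied_fraction

    def test_invariants_and_errors(self):
        m = JacksonModel(6.0, 20, 1.0)  # psi = 0.3
        res = simulate_network(m, horizon=200.0, warmup=20.0, seed=5)
        assert 0 <= res.queue_fraction <= res.occupied_fraction <= 1
        assert res.state_histogram.sum() == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(ValueError):
            simulate_network(m, horizon=10.0, warmup=10.0)

    @pytest.mark.parametrize("psi", [0.05, 0.3, 0.7])
    def test_occupancy_matches_closed_form(self, psi):
        """Time-averaged busy fraction and mean queue length agree with the
        geometric equilibrium (psi and psi/(1-psi)) within 3 SE, pooling
        five independent seeds."""
        n, d = 20, 0.5
        m = JacksonModel(psi * n / d, n, d)
        occ, mean_n, ses = [], [], []
        for seed in range(5):
            res = simulate_network(m, horizon=220.0, warmup=20.0, seed=seed)
            occ.append(res.occupied_fraction)
            mean_n.append(res.mean_in_system)
            ses.append(res.occupied_fraction_se)
        se_pooled = np.sqrt(np.mean(np.square(ses))) / np.sqrt(5)
        assert np.mean(occ) == pytest.approx(psi, abs=3 * se_pooled)
        expected_n = psi / (1 - psi)
        assert np.mean(mean_n) == pytest.approx(expected_n, rel=0.12)

    def test_littles_law(self):
        m = JacksonModel(6.0, 20, 1.0)  # psi = 0.3 per server
        res = simulate_network(m, horizon=1500.0, warmup=50.0, seed=7)
        arrival_rate_per_server = m.flux_lambda / m.n_servers
        assert res.mean_in_system == pytest.approx(
            arrival_rate_per_server * res.mean_sojourn, rel=0.05
        )

    def test_state_histogram_close_to_geometric(self):
        m = JacksonModel(6.0, 20, 1.0)  # psi = 0.3
        res = simulate_network(m, horizon=400.0, warmup=40.0, seed=2)
        expected = state_distribution(0.3, k_max=len(res.state_histogram) - 1).pmf
        assert np.abs(res.state_histogram - expected).max() < 0.02


class TestSnapshotCensus:
    def test_empty_at_zero_occupancy(self):
        m = JacksonModel(LAM, 110, 0.0)
        table = snapshot_census(m, 500, seed=1)
        assert table.npcs_with_particles == 0
        assert table.total_particles == 0

    def test_wild_type_census_scale(self):
        """At psi = 0.054, 818 snapshots give ~44 occupied NPCs (3 sigma)."""
        m = JacksonModel(LAM, 110, invert_dwell_time(0.054, 110, LAM))
        table = snapshot_census(m, 818, seed=4)
        sigma = math.sqrt(818 * 0.054 * 0.946)
        assert abs(table.npcs_with_particles - 818 * 0.054) <= 3 * sigma

    def test_single_occupancy_fraction_at_half(self):
        m = JacksonModel(1.0, 2, 1.0)  # psi = 0.5
        n = 100_000
        table = snapshot_census(m, n, seed=8)
        frac_one = table.npcs_1_particle / n
        sigma = math.sqrt(0.25 * 0.75 / n)
        assert abs(frac_one - 0.25) <= 3 * sigma

    def test_invalid_snapshot_count(self):
        with pytest.raises(ValueError):
            snapshot_census(JacksonModel(1.0, 2, 1.0), 0)


class TestDwellTimeModel:
    def test_fit_reproduces_headline_numbers(self):
        res = DwellTimeModel(44, 818).fit()
        assert round(res.dwell_ms) == 89
        assert res.queue_probability == pytest.approx(res.psi**2)
        lo, hi = res.dwell_ci_ms
        assert lo < res.dwell_ms < hi

    def test_summary_mentions_key_quantities(self):
        text = DwellTimeModel(44, 818).fit().summary()
        assert "nearest ms: 89" in text
        assert "110" in text
        assert "P(queue)" in text
        assert "44 / 818" in text

    def test_simulation_hangs_off_results(self):
        res = DwellTimeModel(44, 818).fit()
        sim = res.simulate(horizon=30.0, warmup=2.0, seed=0)
        assert isinstance(sim, SimulationResult)
        assert 0 < sim.occupied_fraction < 0.2

    def test_occupancy_ci_brackets_psi(self):
        res = DwellTimeModel(44, 818).fit()
        lo, hi = res.psi_ci
        assert lo < 44 / 818 < hi
        # exact binomial CI, cross-checked against the beta quantile form
        assert lo == pytest.approx(sps.beta.ppf(0.025, 44, 818 - 44 + 1), abs=1e-9)
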