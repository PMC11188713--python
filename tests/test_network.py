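"""Network construction and integration invariants."""

import numpy as np
import pytest

from striatnet.cell import CellParams, DriveSpec, simulate_cell
from striatnet.network import (NetworkParams, build_network, run_network,
                               sample_sweep)


class TestBuild:
    def test_reproducible_from_seed(self):
        p = NetworkParams(n_cells=50, seed=3)
        a, b = build_network(p), build_network(p)
        assert np.array_equal(a.targets, b.targets)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.drives, b.drives)

    def test_zero_probability_gives_no_edges(self):
        net = build_network(NetworkParams(n_cells=30, p_connect=0.0, seed=1))
        assert net.n_edges == 0

    def test_full_scale_mean_degree_near_160(self):
        net = build_network(NetworkParams(n_cells=400, seed=0))
        # expectation (N-1) p = 159.6; binomial SE over 400 cells ~ 0.5
        assert net.mean_in_degree == pytest.approx(159.6, abs=2.0)

    def test_no_self_connections(self):
        net = build_network(NetworkParams(n_cells=40, seed=2))
        src = np.repeat(np.arange(40), np.diff(net.indptr))
        assert (src != net.targets).all()

    def test_draws_within_stated_intervals(self):
        p = NetworkParams(n_cells=60, g_i=0.012, g_e=1.5e-5, seed=5)
        net = build_network(p)
        assert (net.weights >= 0.3125 * p.g_i).all()
        assert (net.weights <= 0.9375 * p.g_i).all()
        assert (net.delays_ms >= 1.0).all() and (net.delays_ms <= 3.0).all()
        assert (net.drives >= 0.001305).all()
        assert (net.drives <= 0.001305 + p.g_e).all()

    def test_rejects_out_of_range_parameters(self):
        with pytest.raises(ValueError):
            NetworkParams(g_i=0.05)
        with pytest.raises(ValueError):
            NetworkParams(g_e=1e-4)
        with pytest.raises(ValueError):
            NetworkParams(p_connect=1.5)


class TestRun:
    def test_single_cell_reduces_to_isolated_simulation(self):
        p = NetworkParams(n_cells=1, g_i=0.0, g_e=0.0, duration_s=5.0, seed=9)
        net = build_network(p)
        raster = run_network(net)
        trace = simulate_cell(CellParams(), DriveSpec(increment=0.0,
                                                      duration_s=5.0))
        assert np.array_equal(raster.times_ms, trace.spike_times)

    def test_spike_conservation_and_ordering(self, small_net_raster):
        _, raster = small_net_raster
        assert (raster.times_ms >= 0).all()
        assert (raster.times_ms <= raster.duration_ms).all()
        for c in range(0, raster.n_cells, 13):
            assert (np.diff(raster.times_for(c)) > 0).all()

    def test_uninhibited_rates_match_isolated_cell(self):
        p = NetworkParams(n_cells=15, g_i=0.0, g_e=2e-5, duration_s=10.0, seed=4)
        net = build_network(p)
        raster = run_network(net)
        rates = raster.rates_hz()
        cp = CellParams()
        for c in (0, 7, 14):
            iso = simulate_cell(cp, DriveSpec(
                base=net.drives[c], increment=0.0, duration_s=10.0))
            assert rates[c] == pytest.approx(iso.rate_hz, rel=0.02, abs=0.11)

    def test_population_rate_capped_by_max_fi(self):
        p = NetworkParams(n_cells=15, g_i=0.0, g_e=2e-5, duration_s=10.0, seed=4)
        raster = run_network(build_network(p))
        assert raster.rates_hz().mean() <= 10.5

    def test_inhibition_monotonically_suppresses(self):
        for seed in (11, 12):
            totals = []
            for gi in (0.004, 0.012, 0.02):
                p = NetworkParams(n_cells=40, g_i=gi, g_e=1e-5,
                                  duration_s=20.0, seed=seed)
                totals.append(run_network(build_network(p)).n_spikes)
            assert totals[0] >= totals[1] >= totals[2]

    def test_mid_range_regime_has_bursty_intervals(self):
        from striatnet.features import binarize, feature_vector

        p = NetworkParams(n_cells=100, g_i=0.009, g_e=1e-5,
                          duration_s=60.0, seed=21)
        raster = run_network(build_network(p))
        fv = feature_vector(binarize(raster))
        assert fv.interval_cv > 1.0


class TestSweep:
    def test_inside_prior_box_and_reproducible(self):
        a = sample_sweep(200, seed=8)
        b = sample_sweep(200, seed=8)
        assert np.array_equal(a, b)
        assert a.shape == (200, 2)
        assert (a[:, 0] >= 0.002).all() and (a[:, 0] <= 0.02).all()
        assert (a[:, 1] >= 0.0).all() and (a[:, 1] <= 2e-5).all()

    def test_means_near_box_center(self):
        s = sample_sweep(2000, seed=0)
        assert s[:, 0].mean() == pytest.approx(0.011, abs=4e-4)
        assert s[:, 1].mean() == pytest.approx(1e-5, abs=4e-7)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            sample_sweep(0)
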