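"""Calcium raster construction and summary features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from striatnet.features import (CaRaster, activation_intervals, binarize,
                                feature_vector, total_fluctuation, wta_filter)
from striatnet.network import SpikeRaster


def raster_from(mat):
    mat = np.asarray(mat, dtype=np.uint8)
    return CaRaster(matrix=mat, cell_indices=np.arange(mat.shape[0]))


def spikes(cells, times, n_cells, duration_ms):
    return SpikeRaster(cells=np.asarray(cells, np.int64),
                       times_ms=np.asarray(times, float),
                       n_cells=n_cells, duration_ms=duration_ms)


class TestBinarize:
    def test_direct_binning(self):
        ca = binarize(spikes([0, 0, 0], [10.0, 60.0, 300.0], 1, 1000.0))
        assert ca.matrix.tolist() == [[1, 1, 0, 0]]

    def test_silent_cells_dropped_but_recorded(self):
        ca = binarize(spikes([0], [10.0], 3, 1000.0))
        assert ca.n_active == 1
        assert ca.cell_indices.tolist() == [0]
        assert ca.n_cells_total == 3

    def test_boundary_spike_goes_to_later_bin(self):
        ca = binarize(spikes([0], [250.0], 1, 1000.0))
        assert ca.matrix.tolist() == [[0, 1, 0, 0]]

    def test_out_of_range_times_rejected(self):
        with pytest.raises(ValueError):
            binarize(spikes([0], [-1.0], 1, 1000.0))
        with pytest.raises(ValueError):
            binarize(spikes([0], [1500.0], 1, 1000.0))

    def test_activity_conservation(self, rng):
        n_cells, dur = 10, 5000.0
        cells = rng.integers(0, n_cells, 200)
        times = rng.uniform(0, dur, 200)
        ca = binarize(spikes(cells, times, n_cells, dur))
        occupied = {(c, int(t // 250)) for c, t in zip(cells, times)}
        assert ca.matrix.sum() == len(occupied)


class TestIntervals:
    def test_hand_example(self):
        assert activation_intervals([1, 1, 0, 1]).tolist() == [0, 1]

    def test_single_active_bin_has_no_intervals(self):
        assert activation_intervals([0, 1, 0]).size == 0

    def test_all_active_gives_zero_intervals(self):
        assert activation_intervals([1, 1, 1, 1]).tolist() == [0, 0, 0]

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            activation_intervals([0, 2, 1])
        with pytest.raises(ValueError):
            activation_intervals([])

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=1000)
    def test_against_brute_force_scan(self, row):
        # independent oracle: walk the row and count gaps directly
        expected, last = [], None
        for i, v in enumerate(row):
            if v:
                if last is not None:
                    expected.append(i - last - 1)
                last = i
        assert activation_intervals(row).tolist() == expected


class TestFeatureVector:
    def test_all_ones(self):
        fv = feature_vector(raster_from(np.ones((3, 8))))
        assert (fv.activity, fv.interval, fv.interval_cv) == (1.0, 0.0, 0.0)

    def test_two_cell_toy_example(self):
        # hand-computed gaps: row (1,0,1,0,1,0) -> [1,1];
        # row (1,1,0,0,1,1) -> [0,2,0]
        fv = feature_vector(raster_from([[1, 0, 1, 0, 1, 0],
                                         [1, 1, 0, 0, 1, 1]]))
        assert fv.activity == pytest.approx((0.5 + 4 / 6) / 2)
        assert fv.interval == pytest.approx((1.0 + 2 / 3) / 2)
        assert fv.interval_cv == pytest.approx((0.0 + np.sqrt(2)) / 2)

    def test_exactly_invariant_under_percell_time_shifts(self, rng):
        # each cell's activity confined to the middle; independent per-cell
        # translations then leave all three features exactly unchanged
        mat = np.zeros((20, 100), dtype=np.uint8)
        mat[:, 30:70] = (rng.random((20, 40)) < 0.3).astype(np.uint8)
        mat[mat.sum(axis=1) == 0, 40] = 1
        shifts = rng.integers(-25, 26, 20)
        shifted = np.array([np.roll(r, int(s)) for r, s in zip(mat, shifts)])
        a = feature_vector(raster_from(mat))
        b = feature_vector(raster_from(shifted))
        assert a.as_array().tolist() == b.as_array().tolist()

    def test_activity_invariant_under_circular_shifts(self, rng):
        mat = (rng.random((20, 80)) < 0.3).astype(np.uint8)
        mat[mat.sum(axis=1) == 0, 0] = 1
        shifted = np.array([np.roll(r, int(s)) for r, s in
                            zip(mat, rng.integers(0, 80, 20))])
        assert (feature_vector(raster_from(mat)).activity
                == feature_vector(raster_from(shifted)).activity)

    def test_adding_silent_cell_changes_nothing(self, rng):
        cells = rng.integers(0, 5, 100)
        times = rng.uniform(0, 10000.0, 100)
        a = feature_vector(binarize(spikes(cells, times, 5, 10000.0)))
        b = feature_vector(binarize(spikes(cells, times, 6, 10000.0)))
        assert a.as_array().tolist() == b.as_array().tolist()

    def test_empty_raster_rejected(self):
        with pytest.raises(ValueError):
            feature_vector(CaRaster(matrix=np.zeros((0, 10), dtype=np.uint8),
                                    cell_indices=np.zeros(0, dtype=np.int64)))


class TestTotalFluctuation:
    def test_constant_population_activity_is_zero(self):
        qc = total_fluctuation(raster_from(np.ones((5, 200))), transient_bins=20)
        assert qc.total_fluctuation == 0.0

    def test_alternating_all_on_off_gives_cv_one(self):
        mat = np.zeros((4, 100), dtype=np.uint8)
        mat[:, ::2] = 1
        qc = total_fluctuation(raster_from(mat), transient_bins=0)
        assert qc.total_fluctuation == pytest.approx(1.0)

    def test_dead_network_flagged(self):
        mat = np.zeros((3, 200), dtype=np.uint8)
        mat[:, 5] = 1  # only active inside the transient
        qc = total_fluctuation(raster_from(mat), transient_bins=50)
        assert qc.total_fluctuation == 0.0
        assert qc.dead

    def test_requires_enough_bins(self):
        with pytest.raises(ValueError):
            total_fluctuation(raster_from(np.ones((2, 100))), transient_bins=95)

    def test_depends_on_cell_subsampling(self, rng):
        mat = (rng.random((60, 300)) < 0.3).astype(np.uint8)
        full = total_fluctuation(raster_from(mat), 0).total_fluctuation
        sub = total_fluctuation(raster_from(mat[:8]), 0).total_fluctuation
        assert full != sub


class TestWTAFilter:
    def make(self, fluct):
        from striatnet.features import FeatureVector, QCMetrics

        return ((0.01, 1e-5), FeatureVector(0.5, 1.0, 1.0),
                QCMetrics(fluct, 10, 0))

    def test_threshold_semantics(self):
        recs = [self.make(f) for f in (0.05, 0.09, 0.50)]
        kept, removed = wta_filter(recs)
        assert [r[2].total_fluctuation for r in removed] == [0.05]
        assert [r[2].total_fluctuation for r in kept] == [0.09, 0.50]
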