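"""Calcium-like binary rasters and the summary features used for inference.

Spike trains are binned into 250 ms windows and binarized (>= 1 spike), the
temporal resolution at which somatic calcium imaging reports bursts of
spiking.  Cells that never spike are dropped, mirroring the treatment of
never-active regions of interest in slice recordings.

Three per-cell statistics, averaged over active cells, summarize a raster
for simulation-based inference:

* mean activity — fraction of active bins;
* mean activation interval — mean gap (in bins) between consecutive active
  bins, where adjacent active bins count as a zero interval;
* interval CV — SD/mean of those gaps.

A fourth quantity, the *total fluctuation* (CV of the population-mean
activity time series after discarding an initial transient), is a
quality-control statistic only: it is identically zero for a network frozen
into a winners-take-all (WTA) fixed point, and simulations below 0.09 are
excluded from training.  Unlike the three features it depends strongly on
the number of recorded cells, so it is never used as a feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SpikeRaster

BIN_MS = 250.0
WTA_THRESHOLD = 0.09
DEFAULT_TRANSIENT_BINS = 120  # 30 s


@dataclass
class CaRaster:
    """Binary activity matrix, active cells x 250 ms bins."""

    matrix: np.ndarray  # uint8, entries in {0, 1}
    cell_indices: np.ndarray  # original indices of the retained cells
    bin_ms: float = BIN_MS
    n_cells_total: int | None = None

    @property
    def n_active(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def duration_ms(self) -> float:
        return self.n_bins * self.bin_ms


@dataclass
class FeatureVector:
    """Cell-averaged summary features of a calcium raster."""

    activity: float
    interval: float  # bins
    interval_cv: float

    def as_array(self) -> np.ndarray:
        return np.array([self.activity, self.interval, self.interval_cv])


@dataclass
class QCMetrics:
    """Quality-control statistics of a raster."""

    total_fluctuation: float
    n_active: int
    transient_bins: int
    dead: bool = False  # population activity identically zero after transient


def binarize(spikes: SpikeRaster, bin_ms: float = BIN_MS) -> CaRaster:
    """Bin and binarize a spike raster; silent cells are dropped.

    Bin b of cell c is 1 iff the cell spiked in [b*bin, (b+1)*bin) ms; a
    spike at exactly the recording end is assigned to the last bin.
    """
    n_bins = int(spikes.duration_ms // bin_ms)
    if n_bins < 1:
        raise ValueError("recording shorter than one bin")
    t = spikes.times_ms
    if t.size and (t.min() < 0 or t.max() > spikes.duration_ms):
        raise ValueError("spike times outside [0, duration]")
    b = np.minimum((t // bin_ms).astype(np.int64), n_bins - 1)
    full = np.zeros((spikes.n_cells, n_bins), dtype=np.uint8)
    full[spikes.cells, b] = 1
    active = np.flatnonzero(full.any(axis=1))
    return CaRaster(
        matrix=full[active],
        cell_indices=active,
        bin_ms=bin_ms,
        n_cells_total=spikes.n_cells,
    )


def activation_intervals(row: np.ndarray) -> np.ndarray:
    """Gaps (in bins) between consecutive active bins of one binary row.

    Adjacent active bins yield a zero interval; fewer than two active bins
    yield no intervals.
    """
    row = np.asarray(row)
    if row.size == 0:
        raise ValueError("row is empty")
    if not np.isin(row, (0, 1)).all():
        raise ValueError("row must be binary")
    on = np.flatnonzero(row)
    if on.size < 2:
        return np.zeros(0, dtype=np.int64)
    return np.diff(on) - 1


def _interval_stats(row: np.ndarray) -> tuple[float, float]:
    """Mean and CV of the activation gaps of one row.

    Gaps are the linear-scan intervals between consecutive active bins
    (``activation_intervals``); the stretch before the first activation —
    e.g. the spiking-onset latency — is deliberately not a gap.  Cells with
    fewer than two active bins contribute no intervals and enter the
    averages as 0; a zero mean gap (all-adjacent activations) has CV 0.
    """
    on = np.flatnonzero(row)
    if on.size < 2:
        return 0.0, 0.0
    iv = np.diff(on) - 1
    mean = iv.mean()
    if mean == 0.0:
        return 0.0, 0.0
    return float(mean), float(iv.std() / mean)


def feature_vector(raster: CaRaster) -> FeatureVector:
    """The three cell-averaged summary features of a raster.

    Per-cell mean activity, mean activation interval and interval CV are
    each averaged across active cells; cells with fewer than two active
    bins contribute 0 to the interval and CV averages.  All three features
    are exactly invariant to temporal translations of individual cells'
    rows (activity is additionally invariant to circular shifts).
    """
    if raster.n_active == 0:
        raise ValueError("raster has no active cells")
    act = raster.matrix.mean(axis=1)
    stats = np.array([_interval_stats(r) for r in raster.matrix])
    return FeatureVector(
        activity=float(act.mean()),
        interval=float(stats[:, 0].mean()),
        interval_cv=float(stats[:, 1].mean()),
    )


def total_fluctuation(
    raster: CaRaster, transient_bins: int = DEFAULT_TRANSIENT_BINS
) -> QCMetrics:
    """CV of the population-mean activity series after the transient.

    Zero (with the ``dead`` flag) when the mean activity is identically
    zero, and zero for any constant population trace — the signature of a
    WTA fixed point.
    """
    if raster.n_bins - transient_bins < 10:
        raise ValueError("fewer than 10 bins after transient removal")
    pop = raster.matrix[:, transient_bins:].mean(axis=0)
    m = pop.mean()
    if m == 0.0:
        return QCMetrics(0.0, raster.n_active, transient_bins, dead=True)
    return QCMetrics(float(pop.std() / m), raster.n_active, transient_bins)


def wta_filter(records: list, threshold: float = WTA_THRESHOLD):
    """Split records into (kept, removed) by total fluctuation.

    Each record is a (params, FeatureVector, QCMetrics) triple; records with
    total fluctuation strictly below the threshold are removed (the
    boundary value itself is kept).
    """
    kept, removed = [], []
    for rec in records:
        qc = rec[2]
        (kept if qc.total_fluctuation >= threshold else removed).append(rec)
    return kept, removed
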