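"""Random inhibitory MSN network: construction, integration, parameter sweeps.

The striatal model is a directed Erdos-Renyi network of identical MSN cells
(default 400 cells, connection probability 0.4, hence ~160 inputs per cell)
coupled by depressing/facilitating GABA synapses.  Two scalar parameters
set the operating point:

* ``G_I`` — lateral inhibition scale; each synaptic weight is drawn
  uniformly from [0.3125 G_I, 0.9375 G_I].
* ``G_E`` — excitatory drive scale; each cell receives a constant somatic
  drive drawn uniformly from [0.001305, 0.001305 + G_E], fixed for the run.

Axonal delays are uniform in 1-3 ms.  Dynamics are fully deterministic
given the built network: all fluctuations are network-generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .cell import BASE_DRIVE, GE_MAX, CellParams, IntegrationError, settle
from .synapse import TMParams, weight_to_conductance

GI_MIN, GI_MAX = 0.002, 0.02
PRIOR_BOX = ((GI_MIN, GI_MAX), (0.0, GE_MAX))


@dataclass
class NetworkParams:
    """Construction parameters of the MSN network."""

    n_cells: int = 400
    p_connect: float = 0.4
    g_i: float = 0.008
    g_e: float = 1.0e-5
    weight_frac: tuple[float, float] = (0.3125, 0.9375)
    delay_ms: tuple[float, float] = (1.0, 3.0)
    duration_s: float = 600.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_connect <= 1.0:
            raise ValueError("connection probability must lie in [0, 1]")
        if not 0.0 <= self.g_i <= GI_MAX:
            raise ValueError(f"G_I must lie in [0, {GI_MAX}]")
        if not 0.0 <= self.g_e <= GE_MAX:
            raise ValueError(f"G_E must lie in [0, {GE_MAX}]")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")


@dataclass
class Network:
    """A realized network: topology, per-edge weights/delays, per-cell drives."""

    params: NetworkParams
    indptr: np.ndarray  # CSR over presynaptic cells
    targets: np.ndarray
    weights: np.ndarray  # per-edge, in [0.3125 G_I, 0.9375 G_I]
    delays_ms: np.ndarray  # per-edge, in [1, 3] ms
    drives: np.ndarray  # per-cell total drive (drive units)

    @property
    def n_cells(self) -> int:
        return self.params.n_cells

    @property
    def n_edges(self) -> int:
        return int(self.targets.size)

    @property
    def mean_in_degree(self) -> float:
        if self.n_edges == 0:
            return 0.0
        return self.n_edges / self.n_cells


@dataclass
class SpikeRaster:
    """Flat spike table (cell index, time in ms) over [0, duration]."""

    cells: np.ndarray
    times_ms: np.ndarray
    n_cells: int
    duration_ms: float

    def times_for(self, cell: int) -> np.ndarray:
        return np.sort(self.times_ms[self.cells == cell])

    @property
    def n_spikes(self) -> int:
        return int(self.cells.size)

    def rates_hz(self) -> np.ndarray:
        counts = np.bincount(self.cells, minlength=self.n_cells)
        return counts / (self.duration_ms / 1000.0)


def build_network(params: NetworkParams, seed: int | None = None) -> Network:
    """Draw topology, weights, delays and drives from per-purpose RNG streams.

    Each ordered pair (i, j), i != j, is connected independently with the
    stated probability.  The four draw classes (topology, weights, delays,
    drives) use independent child streams of the master seed, so any one can
    be held fixed while others vary.
    """
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_top, rng_w, rng_d, rng_drv = [np.random.default_rng(s) for s in ss.spawn(4)]
    n = params.n_cells
    adj = rng_top.random((n, n)) < params.p_connect
    np.fill_diagonal(adj, False)
    indptr = np.zeros(n + 1, dtype=np.int64)
    indptr[1:] = np.cumsum(adj.sum(axis=1))
    targets = np.flatnonzero(adj.ravel()) % n
    targets = targets.astype(np.int64)
    m = targets.size
    lo, hi = params.weight_frac
    weights = rng_w.uniform(lo * params.g_i, hi * params.g_i, size=m)
    delays = rng_d.uniform(*params.delay_ms, size=m)
    drives = rng_drv.uniform(BASE_DRIVE, BASE_DRIVE + params.g_e, size=n)
    return Network(params, indptr, targets, weights, delays, drives)


def run_network(
    net: Network,
    duration_s: float | None = None,
    dt: float = 0.025,
    cell_params: CellParams | None = None,
    tm: TMParams = TMParams(),
) -> SpikeRaster:
    """Integrate the network; returns the spike raster.

    Every cell starts from the common 2 s drive-free resting state; the
    synaptic conductance transient of each presynaptic spike is
    phi(w) * R * S, delivered after the edge delay (rounded to the grid).
    Deterministic given (net, dt).
    """
    if dt > 0.1:
        raise ValueError("dt must be <= 0.1 ms")
    p = cell_params or CellParams()
    duration_s = net.params.duration_s if duration_s is None else duration_s
    duration_ms = duration_s * 1000.0
    n = net.n_cells

    rest = settle(p, dt)
    state = np.repeat(rest, n, axis=1)
    tm_state = np.zeros((3, n))
    tm_state[0] = 1.0
    tm_state[2] = -1e9

    tab = p.tables()
    i_ext = net.drives * p.drive_scale
    g_inc = np.asarray(weight_to_conductance(net.weights), dtype=float)
    delay_steps = np.maximum(1, np.rint(net.delays_ms / dt)).astype(np.int64)
    n_steps = int(round(duration_ms / dt))
    cap = int(n * duration_s * 20) + 1000
    spk_cell = np.zeros(cap, dtype=np.int64)
    spk_time = np.zeros(cap)
    empty_i = np.zeros(0, dtype=np.int64)
    v_rec = np.zeros((1, 0))
    status, n_spk, err_step, err_cell = K.run_net(
        n_steps, dt, tab, p.gmax, p.erev, p.cm, p.taus,
        state, i_ext, tm.e_gaba_mv, tm.tau_syn_ms,
        net.indptr, net.targets, g_inc, delay_steps,
        tm.u, tm.d_ms, tm.f_ms, tm_state,
        empty_i, empty_i, np.zeros(0),
        spk_cell, spk_time, v_rec, np.zeros(1, dtype=np.int64), 0, 0.0,
    )
    if status != K.OK:
        raise IntegrationError(err_step, err_cell, dt)
    return SpikeRaster(
        cells=spk_cell[:n_spk].copy(),
        times_ms=spk_time[:n_spk].copy(),
        n_cells=n,
        duration_ms=duration_ms,
    )


def sample_sweep(n: int = 200, ranges=PRIOR_BOX, seed: int = 0) -> np.ndarray:
    """Draw n i.i.d. uniform (G_I, G_E) pairs from the prior box."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    (gi_lo, gi_hi), (ge_lo, ge_hi) = ranges
    out = np.empty((n, 2))
    out[:, 0] = rng.uniform(gi_lo, gi_hi, n)
    out[:, 1] = rng.uniform(ge_lo, ge_hi, n)
    return out
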