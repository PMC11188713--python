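"""Single-compartment medium spiny neuron (MSN) model.

MSNs are the GABAergic projection neurons of the striatum.  Their hallmark
electrophysiology — a hyperpolarized resting potential maintained by inward
rectification, a long ramp-like delay to the first spike under current
injection, and low tonic firing rates — is reproduced here by a
single-compartment conductance model carrying the classic MSN current
complement: fast sodium I_Na and delayed-rectifier I_K for spike generation,
inward rectifier I_Kir, fast and slow A-type potassium currents I_Af and
I_As, a persistent potassium current I_Krp, and persistent plus slow sodium
currents I_NaP and I_NaS.  The slowly inactivating potassium currents oppose
depolarization at stimulus onset and give the characteristic first-spike
latency of hundreds of milliseconds near threshold.

Excitatory drive is expressed in abstract "drive units": the somatic current
is ``drive * drive_scale`` (uA/cm^2).  The scale and the peak conductances
are calibrated once so that the standard network drive range
[0.001305, 0.001305 + 2e-5] spans suprathreshold firing up to roughly 10 Hz,
with the rheobase just below the bottom of the range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K

#: channel names, in the fixed order used throughout the package
CHANNELS = ("I_Na", "I_K", "I_Kir", "I_Af", "I_As", "I_Krp", "I_NaP", "I_NaS")

#: standard base drive (drive units) shared by every cell in the network
BASE_DRIVE = 0.001305
#: maximum excitatory increment G_E explored by the model
GE_MAX = 2.0e-5

#: gating kinetics: (vhalf, slope) per table row; slope < 0 inactivates
DEFAULT_KINETICS = np.array(
    [
        (-35.0, 8.0),   # m_Na (instantaneous, cubed)
        (-55.0, -7.0),  # h_Na
        (-32.0, 8.0),   # n_K (squared)
        (-100.0, -10.0),  # Kir (instantaneous)
        (-45.0, 12.0),  # a_Af
        (-75.0, -7.0),  # h_Af
        (-40.0, 10.0),  # a_As (instantaneous)
        (-70.0, -8.0),  # h_As (slow inactivation -> first-spike delay)
        (-25.0, 12.0),  # p_Krp (instantaneous, non-inactivating)
        (-48.0, -3.5),  # m_NaP (instantaneous)  [slope sign fixed below]
        (-40.0, 6.0),   # m_NaS (slow activation)
    ]
)
DEFAULT_KINETICS[9] = (-48.0, 3.5)

#: time constants (ms) of the six dynamic gates: h_Na, n_K, a_Af, h_Af, h_As, m_NaS
DEFAULT_TAUS = np.array([1.2, 2.5, 1.0, 25.0, 400.0, 150.0])


class IntegrationError(RuntimeError):
    """Raised when the membrane state becomes non-finite during integration."""

    def __init__(self, step: int, cell: int, dt: float):
        self.step = step
        self.cell = cell
        super().__init__(
            f"non-finite membrane state at step {step} (t = {step * dt:.3f} ms)"
            f" in cell {cell}"
        )


class CalibrationError(RuntimeError):
    pass


@dataclass
class CellParams:
    """MSN membrane parameters.

    Conductances in mS/cm^2, reversals in mV, capacitance in uF/cm^2.
    ``drive_scale`` converts abstract drive units to uA/cm^2.
    """

    g_na: float = 35.0
    g_k: float = 8.0
    g_kir: float = 0.12
    g_af: float = 0.20
    g_as: float = 0.20
    g_krp: float = 0.10
    g_nap: float = 0.010
    g_nas: float = 0.005
    g_leak: float = 0.02
    e_na: float = 55.0
    e_k: float = -90.0
    e_leak: float = -75.0
    cm: float = 1.0
    temperature: float = 35.0
    drive_scale: float = 942.7382
    kinetics_tag: str = "boltzmann-msn-v1"
    kinetics: np.ndarray = field(default_factory=lambda: DEFAULT_KINETICS.copy())
    taus: np.ndarray = field(default_factory=lambda: DEFAULT_TAUS.copy())

    def __post_init__(self):
        for name in ("g_na", "g_k", "g_kir", "g_af", "g_as", "g_krp",
                     "g_nap", "g_nas", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.drive_scale <= 0:
            raise ValueError("drive_scale must be > 0")

    @property
    def gmax(self) -> np.ndarray:
        return np.array(
            [self.g_na, self.g_k, self.g_kir, self.g_af, self.g_as,
             self.g_krp, self.g_nap, self.g_nas, self.g_leak]
        )

    @property
    def erev(self) -> np.ndarray:
        return np.array([self.e_na, self.e_k, self.e_leak])

    def tables(self) -> np.ndarray:
        return K.build_gate_tables(self.kinetics)


@dataclass
class DriveSpec:
    """Constant somatic drive: base amplitude plus an excitatory increment."""

    base: float = BASE_DRIVE
    increment: float = 0.0
    duration_s: float = 10.0

    def __post_init__(self):
        if self.base <= 0:
            raise ValueError("drive base must be > 0")
        if not 0.0 <= self.increment <= GE_MAX:
            raise ValueError(f"drive increment must lie in [0, {GE_MAX}]")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")

    @property
    def total(self) -> float:
        return self.base + self.increment


@dataclass
class VoltageTrace:
    """Membrane trajectory with detected spike times (upward 0 mV crossings)."""

    t: np.ndarray  # ms
    v: np.ndarray  # mV
    spike_times: np.ndarray  # ms, strictly increasing
    dt: float
    duration_ms: float

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def rate_hz(self) -> float:
        return self.n_spikes / (self.duration_ms / 1000.0)

    @property
    def first_spike_latency_ms(self) -> float:
        """Latency from stimulus onset to the first spike (inf if none)."""
        return float(self.spike_times[0]) if self.n_spikes else float("inf")


SETTLE_MS = 2000.0


def _run_single(
    params: CellParams,
    current: float,
    duration_ms: float,
    dt: float,
    state: np.ndarray | None = None,
    record: bool = True,
    rec_stride: int = 4,
    syn_events: tuple[np.ndarray, np.ndarray] | None = None,
    e_gaba: float = -85.0,
    t0: float = 0.0,
):
    """Integrate one isolated cell; returns (spikes, v_rec, state)."""
    tab = params.tables()
    if state is None:
        state = K.steady_gates(params.kinetics, -80.0).reshape(8, 1).copy()
    n_steps = int(round(duration_ms / dt))
    i_ext = np.array([current])
    empty = np.zeros(0, dtype=np.int64)
    if syn_events is None:
        ev_step, ev_g = empty, np.zeros(0)
    else:
        ev_step, ev_g = syn_events
    ev_cell = np.zeros(ev_step.size, dtype=np.int64)
    cap = max(64, int(duration_ms / 1000.0 * 100))
    spk_cell = np.zeros(cap, dtype=np.int64)
    spk_time = np.zeros(cap)
    if record:
        n_rec = (n_steps + rec_stride - 1) // rec_stride
        v_rec = np.zeros((1, n_rec))
        rec_cells = np.zeros(1, dtype=np.int64)
    else:
        v_rec = np.zeros((1, 0))
        rec_cells = np.zeros(1, dtype=np.int64)
        rec_stride = 0
    tm_state = np.zeros((3, 1))
    tm_state[0] = 1.0
    tm_state[2] = -1e9
    status, n_spk, err_step, err_cell = K.run_net(
        n_steps, dt, tab, params.gmax, params.erev, params.cm, params.taus,
        state, i_ext, e_gaba, 20.0,
        np.zeros(2, dtype=np.int64), empty, np.zeros(0), empty,
        0.41, 222.0, 1859.0, tm_state,
        ev_step, ev_cell, ev_g,
        spk_cell, spk_time, v_rec, rec_cells,
        rec_stride if record else 0, t0,
    )
    if status == K.ERR_NONFINITE:
        raise IntegrationError(err_step, err_cell, dt)
    if status == K.ERR_SPIKE_OVERFLOW:
        raise IntegrationError(err_step, err_cell, dt)
    return spk_time[:n_spk].copy(), (v_rec[0] if record else None), state


def settle(params: CellParams, dt: float = 0.025) -> np.ndarray:
    """Drive-free 2 s settling to the resting state; returns the state vector."""
    _, _, state = _run_single(params, 0.0, SETTLE_MS, dt, record=False)
    return state


def simulate_cell(params: CellParams, drive: DriveSpec, dt: float = 0.025) -> VoltageTrace:
    """Simulate an isolated MSN under constant somatic drive.

    The cell is first settled for 2 s without drive; the returned trace and
    spike times are relative to drive onset.  Deterministic: identical inputs
    give bit-identical output.
    """
    if dt > 0.1:
        raise ValueError("dt must be <= 0.1 ms")
    state = settle(params, dt)
    duration_ms = drive.duration_s * 1000.0
    rec_stride = 4
    spikes, v, _ = _run_single(
        params, drive.total * params.drive_scale, duration_ms, dt,
        state=state, record=True, rec_stride=rec_stride,
    )
    t = np.arange(v.size) * dt * rec_stride
    return VoltageTrace(t=t, v=v, spike_times=spikes, dt=dt, duration_ms=duration_ms)


def _rate(params: CellParams, amp_drive_units: float, duration_s: float,
          dt: float) -> float:
    state = settle(params, dt)
    spikes, _, _ = _run_single(
        params, amp_drive_units * params.drive_scale, duration_s * 1000.0, dt,
        state=state, record=False,
    )
    return spikes.size / duration_s


def fI_curve(params: CellParams, drives: list[DriveSpec], dt: float = 0.025) -> np.ndarray:
    """Firing rate (Hz) for each drive; drives must be sorted ascending."""
    if not drives:
        raise ValueError("drive list is empty")
    totals = [d.total for d in drives]
    if any(b > a for a, b in zip(totals[1:], totals)):
        raise ValueError("drives must be sorted ascending")
    return np.array([_rate(params, d.total, d.duration_s, dt) for d in drives])


def rheobase(params: CellParams, dt: float = 0.025, rtol: float = 1e-3,
             test_duration_s: float = 4.0) -> float:
    """Minimum constant drive (drive units) that elicits spiking, by bisection.

    Near threshold the first-spike latency is long, so spiking is probed over
    a 4 s window.
    """
    state0 = settle(params, dt)

    def spikes_at(amp: float) -> bool:
        spk, _, _ = _run_single(
            params, amp * params.drive_scale, test_duration_s * 1000.0, dt,
            state=state0.copy(), record=False,
        )
        return spk.size > 0

    hi = 2.0 * BASE_DRIVE
    if not spikes_at(hi):
        raise CalibrationError("no spiking even at twice the base drive")
    lo = 0.0
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return hi


def with_params(params: CellParams, **updates) -> CellParams:
    return replace(params, **updates)
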