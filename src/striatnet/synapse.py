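"""Tsodyks-Markram GABA synapse with short-term depression and facilitation.

The deterministic TM model tracks two dimensionless per-synapse variables:
the available resource fraction R (depression, recovery time constant D)
and the utilization S (facilitation, decay time constant F, per-spike
increment set by the utilization factor U).  Between presynaptic spikes both
relax exponentially; at a spike S facilitates first, the conductance
transient is proportional to the product of the pre-spike R and the updated
S, and R is then depleted by that same fraction:

    S+ = S + U * (1 - S)
    g_inc = w_eff * R * S+
    R+ = R * (1 - S+)

Parameters follow striatal MSN-MSN collateral measurements: U = 0.41,
D = 222 ms, F = 1859 ms, conductance decay 20 ms, GABA reversal -85 mV in
the network (-40 mV chloride reversal in the IPSP characterization
protocol), axonal delays 1-3 ms.

The mapping from the abstract synaptic weight w (the network draws
w ~ U[0.3125 G_I, 0.9375 G_I]) to a postsynaptic conductance density is the
calibrated monotone map phi(w) = a w + b w^2; see ``weight_to_conductance``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels as K
from .cell import CellParams, IntegrationError, _run_single

#: calibrated weight -> conductance (mS/cm^2) map coefficients; fixed once
#: against the two single-spike IPSP amplitudes of the characterization
#: protocol (0.1 mV at G_I = 0.002 and 1.5 mV at G_I = 0.02).
PHI_A = 0.5615081007253648
PHI_B = 29.006560962295264


@dataclass(frozen=True)
class TMParams:
    """Short-term plasticity constants of the MSN-MSN GABA synapse."""

    u: float = 0.41
    d_ms: float = 222.0
    f_ms: float = 1859.0
    tau_syn_ms: float = 20.0
    e_gaba_mv: float = -85.0
    delay_min_ms: float = 1.0
    delay_max_ms: float = 3.0

    def __post_init__(self):
        if not 0.0 <= self.u <= 1.0:
            raise ValueError("U must lie in [0, 1]")
        if min(self.d_ms, self.f_ms, self.tau_syn_ms) <= 0:
            raise ValueError("time constants must be > 0")


@dataclass(frozen=True)
class TMState:
    """Instantaneous synapse state: resources R, utilization S, conductance g."""

    r: float = 1.0
    s: float = 0.0
    g: float = 0.0
    t_ms: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.r <= 1.0 and 0.0 <= self.s <= 1.0 and self.g >= 0.0):
            raise ValueError("TM state out of range")


def tm_relax(state: TMState, dt_ms: float, params: TMParams = TMParams()) -> TMState:
    """Spike-free relaxation over ``dt_ms``: R -> 1, S -> 0, g -> 0."""
    if dt_ms < 0:
        raise ValueError("dt must be >= 0")
    ed = np.exp(-dt_ms / params.d_ms)
    ef = np.exp(-dt_ms / params.f_ms)
    eg = np.exp(-dt_ms / params.tau_syn_ms)
    return TMState(
        r=1.0 - (1.0 - state.r) * ed,
        s=state.s * ef,
        g=state.g * eg,
        t_ms=state.t_ms + dt_ms,
    )


def tm_spike(state: TMState, weight: float, params: TMParams = TMParams()) -> TMState:
    """Apply a presynaptic spike; the conductance gains weight * R- * S+."""
    if weight < 0:
        raise ValueError("weight must be >= 0")
    s_plus = state.s + params.u * (1.0 - state.s)
    inc = weight * state.r * s_plus
    return TMState(
        r=state.r * (1.0 - s_plus),
        s=s_plus,
        g=state.g + inc,
        t_ms=state.t_ms,
    )


def steady_state_efficacy(rate_hz: float, params: TMParams = TMParams()) -> float:
    """Mean per-spike efficacy R*S of a periodic train, at the event-map fixed point.

    In the low-rate limit the synapse fully recovers between spikes and the
    efficacy tends to U; at high rates depression dominates.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be > 0")
    dt = 1000.0 / rate_hz
    ef = np.exp(-dt / params.f_ms)
    ed = np.exp(-dt / params.d_ms)
    s_star = params.u / (1.0 - (1.0 - params.u) * ef)
    r_star = (1.0 - ed) / (1.0 - (1.0 - s_star) * ed)
    return r_star * s_star


def weight_to_conductance(weight, a: float | None = None, b: float | None = None):
    """Calibrated map phi(w) from synaptic weight to conductance (mS/cm^2).

    phi(w) = a w + b w^2, monotone on the weight range with phi(0) = 0.  The
    quadratic term absorbs receptor/morphology-level supralinearity that a
    point-conductance synapse does not capture; (a, b) are fixed by the two
    IPSP characterization anchors.
    """
    a = PHI_A if a is None else a
    b = PHI_B if b is None else b
    w = np.asarray(weight, dtype=float)
    return a * w + b * w * w


#: mean of the network weight-fraction range [0.3125, 0.9375]
CHARACTERIZATION_WEIGHT_FRACTION = 0.625

HOLD_MV = -80.0
E_CL_CHARACTERIZATION = -40.0


def holding_current(params: CellParams, v_hold: float = HOLD_MV) -> float:
    """Somatic current (uA/cm^2) holding the cell at ``v_hold`` at equilibrium."""
    kin = params.kinetics
    gates = {row: 1.0 / (1.0 + np.exp(-(v_hold - kin[row, 0]) / kin[row, 1]))
             for row in range(11)}
    g_na = params.g_na * gates[K.M_NA] ** 3 * gates[K.H_NA]
    g_k = params.g_k * gates[K.N_K] ** 2
    g_kir = params.g_kir * gates[K.KIR]
    g_af = params.g_af * gates[K.A_AF] * gates[K.H_AF]
    g_as = params.g_as * gates[K.A_AS] * gates[K.H_AS]
    g_krp = params.g_krp * gates[K.P_KRP]
    g_nap = params.g_nap * gates[K.M_NAP]
    g_nas = params.g_nas * gates[K.M_NAS]
    i_na_like = (g_na + g_nap + g_nas) * (v_hold - params.e_na)
    i_k_like = (g_k + g_kir + g_af + g_as + g_krp) * (v_hold - params.e_k)
    i_leak = params.g_leak * (v_hold - params.e_leak)
    return i_na_like + i_k_like + i_leak


class ProtocolError(RuntimeError):
    pass


def ipsp_response(g_event: float, cell_params: CellParams | None = None,
                  tm: TMParams = TMParams(), dt: float = 0.025,
                  duration_ms: float = 400.0):
    """Voltage response of a -80 mV held cell to one conductance transient.

    The chloride reversal is set to -40 mV, so the IPSP is depolarizing.
    Returns (t_ms, v_mv); the transient is delivered at t = 50 ms.
    """
    p = cell_params or CellParams()
    i_hold = holding_current(p, HOLD_MV)
    state = K.steady_gates(p.kinetics, HOLD_MV).reshape(8, 1).copy()
    ev_step = np.array([int(round(50.0 / dt))], dtype=np.int64)
    ev_g = np.array([g_event])
    _, v, _ = _run_single(
        p, i_hold, duration_ms, dt, state=state, record=True, rec_stride=1,
        syn_events=(ev_step, ev_g), e_gaba=E_CL_CHARACTERIZATION,
    )
    t = np.arange(v.size) * dt
    pre = v[int(40.0 / dt)]
    if abs(pre - HOLD_MV) > 0.1:
        raise ProtocolError(f"cell failed to hold at -80 mV (V = {pre:.2f})")
    return t, v


def ipsp_peak(g_i: float, cell_params: CellParams | None = None,
              tm: TMParams = TMParams(), dt: float = 0.025,
              phi_a: float | None = None, phi_b: float | None = None) -> float:
    """Peak depolarization (mV) from -80 mV after one presynaptic spike.

    Reproduces the IPSP characterization protocol: a single spike from rest
    (R = 1, S = 0 -> efficacy U) through a synapse at the characterization
    weight 0.625 G_I, onto a cell held at -80 mV with chloride reversal
    -40 mV.  Monotone increasing in ``g_i``.
    """
    if g_i < 0:
        raise ValueError("G_I must be >= 0")
    if g_i == 0.0:
        return 0.0
    w = CHARACTERIZATION_WEIGHT_FRACTION * g_i
    g_event = float(weight_to_conductance(w, phi_a, phi_b)) * tm.u
    _, v = ipsp_response(g_event, cell_params, tm, dt)
    return float(v.max() - HOLD_MV)


def calibrate_weight_map(cell_params: CellParams | None = None,
                         anchors=((0.002, 0.1), (0.02, 1.5)),
                         dt: float = 0.025) -> tuple[float, float]:
    """Solve for (a, b) of phi so the two anchor IPSP amplitudes hold exactly.

    For each anchor the required event conductance is found by secant
    iteration on the simulated protocol (the membrane response is nearly,
    but not exactly, linear); the two (weight, conductance) pairs then fix
    the quadratic map uniquely.
    """
    p = cell_params or CellParams()

    def peak_for(g_event):
        _, v = ipsp_response(g_event, p, dt=dt)
        return float(v.max() - HOLD_MV)

    gs = []
    for g_i, target in anchors:
        g0 = 1e-3
        p0 = peak_for(g0)
        g1 = g0 * target / p0
        p1 = peak_for(g1)
        while abs(p1 - target) > 1e-9:
            g2 = g1 + (target - p1) * (g1 - g0) / (p1 - p0)
            g0, p0, g1, p1 = g1, p1, g2, peak_for(g2)
        gs.append(g1)
    tm = TMParams()
    w = np.array([CHARACTERIZATION_WEIGHT_FRACTION * g for g, _ in anchors])
    m = np.column_stack([w, w * w])
    ab = np.linalg.solve(m, np.array(gs) / tm.u)
    return float(ab[0]), float(ab[1])


def _set_phi(a: float, b: float) -> None:
    global PHI_A, PHI_B
    PHI_A, PHI_B = a, b
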