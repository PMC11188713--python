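"""Numba-jitted fixed-step integrator for the MSN network.

All cells share one kinetic scheme: eight voltage-gated currents plus leak,
a GABA-A conductance with exponential decay, and deterministic
Tsodyks-Markram short-term plasticity on the recurrent synapses.  Gating
steady-state curves are evaluated by linear interpolation of precomputed
tables (0.05 mV grid), which keeps the inner loop free of transcendental
calls; gate relaxation uses exponential Euler with fixed time constants and
the membrane equation uses the standard conductance-form exponential update

    V <- V_inf + (V - V_inf) * exp(-g_tot * dt / C).

The integrator is purely deterministic: repeated calls with identical
inputs produce bit-identical trajectories.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# gating-table row layout
M_NA, H_NA, N_K, KIR, A_AF, H_AF, A_AS, H_AS, P_KRP, M_NAP, M_NAS = range(11)

V_MIN = -130.0
V_MAX = 70.0
V_STEP = 0.05

# return codes
OK = 0
ERR_NONFINITE = 1
ERR_SPIKE_OVERFLOW = 2


def _boltz(v: np.ndarray, vhalf: float, k: float) -> np.ndarray:
    """Boltzmann steady-state curve; k < 0 gives an inactivation curve."""
    return 1.0 / (1.0 + np.exp(-(v - vhalf) / k))


def build_gate_tables(kin: np.ndarray) -> np.ndarray:
    """Tabulate the eleven steady-state gating curves on the voltage grid.

    ``kin`` is an (11, 2) array of (vhalf, slope) pairs in the row order of
    the module-level gate indices.
    """
    v = np.arange(V_MIN, V_MAX + V_STEP / 2, V_STEP)
    tab = np.empty((11, v.size))
    for i in range(11):
        tab[i] = _boltz(v, kin[i, 0], kin[i, 1])
    return tab


@njit(cache=True, inline="always")
def _interp(tab, row, v):
    x = (v - V_MIN) / V_STEP
    if x < 0.0:
        x = 0.0
    elif x > tab.shape[1] - 1.001:
        x = tab.shape[1] - 1.001
    i = int(x)
    f = x - i
    return tab[row, i] * (1.0 - f) + tab[row, i + 1] * f


@njit(cache=True)
def run_net(
    n_steps,
    dt,
    tab,
    gmax,  # (9,): gNa gK gKir gAf gAs gKrp gNaP gNaS gLeak
    erev,  # (3,): E_Na E_K E_leak
    cm,
    taus,  # (6,): time constants of hNa, n, aAf, hAf, hAs, mNaS (ms)
    state,  # (8, N): V hNa n aAf hAf hAs mNaS gsyn  (modified in place)
    i_ext,  # (N,) injected current, uA/cm^2
    e_gaba,
    tau_syn,
    indptr,
    targets,
    g_inc,  # per-edge conductance increment scale (phi(w))
    delay_steps,
    tm_u,
    tm_d,
    tm_f,
    tm_state,  # (3, N): R S t_last  (modified in place)
    ev_step,
    ev_cell,
    ev_g,  # external conductance events
    spk_cell,
    spk_time,  # preallocated spike output
    v_rec,  # (n_rec_cells, n_rec_samples) or (0,0)
    rec_cells,
    rec_stride,
    t0,  # time offset (ms) added to recorded spike times
):
    """Integrate the network for ``n_steps`` steps of ``dt`` ms.

    Returns (status, n_spikes, err_step, err_cell).
    """
    n = state.shape[1]
    v = state[0]
    hna = state[1]
    nk = state[2]
    aaf = state[3]
    haf = state[4]
    has_ = state[5]
    mnas = state[6]
    gsyn = state[7]

    # gate relaxation factors (fixed time constants, ms)
    a_hna = 1.0 - math.exp(-dt / taus[0])
    a_nk = 1.0 - math.exp(-dt / taus[1])
    a_aaf = 1.0 - math.exp(-dt / taus[2])
    a_haf = 1.0 - math.exp(-dt / taus[3])
    a_has = 1.0 - math.exp(-dt / taus[4])
    a_nas = 1.0 - math.exp(-dt / taus[5])
    syn_decay = math.exp(-dt / tau_syn)

    e_na = erev[0]
    e_k = erev[1]
    e_leak = erev[2]

    lockout = 2.0  # ms, spike-detection refractory
    thresh = 0.0

    max_delay = 1
    for e in range(delay_steps.size):
        if delay_steps[e] + 1 > max_delay:
            max_delay = delay_steps[e] + 1
    buf = np.zeros((max_delay, n))

    t_last_spk = np.full(n, -1e9)
    prev_v = v.copy()

    n_spk = 0
    cap = spk_cell.size
    n_ev = ev_step.size
    ev_i = 0

    for step in range(n_steps):
        t = (step + 1) * dt

        # deliver delayed synaptic conductance and external events
        row = step % max_delay
        for c in range(n):
            gsyn[c] = gsyn[c] * syn_decay + buf[row, c]
            buf[row, c] = 0.0
        while ev_i < n_ev and ev_step[ev_i] == step:
            gsyn[ev_cell[ev_i]] += ev_g[ev_i]
            ev_i += 1

        for c in range(n):
            vc = v[c]
            m = _interp(tab, M_NA, vc)
            g_na = gmax[0] * m * m * m * hna[c]
            g_k = gmax[1] * nk[c] * nk[c]
            g_kir = gmax[2] * _interp(tab, KIR, vc)
            g_af = gmax[3] * aaf[c] * haf[c]
            g_as = gmax[4] * _interp(tab, A_AS, vc) * has_[c]
            g_krp = gmax[5] * _interp(tab, P_KRP, vc)
            g_nap = gmax[6] * _interp(tab, M_NAP, vc)
            g_nas = gmax[7] * mnas[c]
            g_leak = gmax[8]

            g_tot = (
                g_na + g_k + g_kir + g_af + g_as + g_krp + g_nap + g_nas
                + g_leak + gsyn[c]
            )
            num = (
                (g_na + g_nap + g_nas) * e_na
                + (g_k + g_kir + g_af + g_as + g_krp) * e_k
                + g_leak * e_leak
                + gsyn[c] * e_gaba
                + i_ext[c]
            )
            v_inf = num / g_tot
            prev_v[c] = vc
            v[c] = v_inf + (vc - v_inf) * math.exp(-g_tot * dt / cm)

            if not math.isfinite(v[c]):
                return ERR_NONFINITE, n_spk, step, c

            # gate relaxation toward steady state at the pre-step voltage
            hna[c] += (_interp(tab, H_NA, vc) - hna[c]) * a_hna
            nk[c] += (_interp(tab, N_K, vc) - nk[c]) * a_nk
            aaf[c] += (_interp(tab, A_AF, vc) - aaf[c]) * a_aaf
            haf[c] += (_interp(tab, H_AF, vc) - haf[c]) * a_haf
            has_[c] += (_interp(tab, H_AS, vc) - has_[c]) * a_has
            mnas[c] += (_interp(tab, M_NAS, vc) - mnas[c]) * a_nas

            # upward threshold crossing with lockout
            if prev_v[c] < thresh <= v[c] and t - t_last_spk[c] > lockout:
                t_last_spk[c] = t
                if n_spk >= cap:
                    return ERR_SPIKE_OVERFLOW, n_spk, step, c
                spk_cell[n_spk] = c
                spk_time[n_spk] = t + t0
                n_spk += 1

                # Tsodyks-Markram event update (relax, facilitate, deplete)
                dtm = t - tm_state[2, c]
                r = 1.0 - (1.0 - tm_state[0, c]) * math.exp(-dtm / tm_d)
                s = tm_state[1, c] * math.exp(-dtm / tm_f)
                s = s + tm_u * (1.0 - s)
                rs = r * s
                tm_state[0, c] = r * (1.0 - s)
                tm_state[1, c] = s
                tm_state[2, c] = t
                for e in range(indptr[c], indptr[c + 1]):
                    drow = (step + delay_steps[e]) % max_delay
                    buf[drow, targets[e]] += g_inc[e] * rs

        if rec_stride > 0 and step % rec_stride == 0:
            k = step // rec_stride
            if k < v_rec.shape[1]:
                for j in range(rec_cells.size):
                    v_rec[j, k] = v[rec_cells[j]]

    return OK, n_spk, -1, -1


def steady_gates(kin: np.ndarray, v: float) -> np.ndarray:
    """Gate state vector (7 dynamic gates + gsyn=0) at equilibrium for V=v."""
    s = np.empty(8)
    s[0] = v
    for i, row in enumerate((H_NA, N_K, A_AF, H_AF, H_AS, M_NAS)):
        s[1 + i] = 1.0 / (1.0 + np.exp(-(v - kin[row, 0]) / kin[row, 1]))
    s[7] = 0.0
    return s
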