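"""Reference measurement protocols for the model's calibration surface.

These wrap the library into the handful of deterministic protocols used to
check the model against its published anchors: the single-spike IPSP
amplitudes of the held-cell characterization, the tonic rate of an isolated
cell at the top of the drive range, the mean connectivity of the full-size
network, and the scaled-down winners-take-all transition sweep.
"""

from __future__ import annotations

import numpy as np

from .cell import BASE_DRIVE, GE_MAX, CellParams, DriveSpec, simulate_cell
from .features import binarize, feature_vector
from .network import NetworkParams, build_network, run_network
from .synapse import ipsp_peak

WTA_SWEEP_GIS = (0.003, 0.004, 0.005, 0.006, 0.008, 0.010, 0.012)
WTA_SWEEP_GE = 1.8e-5


def ipsp_amplitude(g_i: float) -> float:
    """Peak single-spike IPSP (mV) under the -80 mV / -40 mV Cl protocol."""
    return ipsp_peak(g_i)


def isolated_rate_at_max_drive(duration_s: float = 10.0) -> float:
    """Tonic rate (Hz) of one MSN at drive 0.001305 + 2e-5, no synapses."""
    trace = simulate_cell(CellParams(),
                          DriveSpec(base=BASE_DRIVE, increment=GE_MAX,
                                    duration_s=duration_s))
    return trace.rate_hz


def full_scale_mean_degree(seed: int = 0) -> float:
    """Mean in-degree of the 400-cell, p = 0.4 network."""
    return build_network(NetworkParams(n_cells=400, seed=seed)).mean_in_degree


def wta_transition_sweep(
    seeds=(1, 2),
    gis=WTA_SWEEP_GIS,
    g_e: float = WTA_SWEEP_GE,
    n_cells: int = 100,
    duration_s: float = 120.0,
):
    """Seed-averaged interval CV across the inhibition grid at high drive.

    Returns (gis, mean_cvs).
    """
    cvs = []
    for gi in gis:
        per_seed = []
        for s in seeds:
            p = NetworkParams(n_cells=n_cells, g_i=gi, g_e=g_e,
                              duration_s=duration_s, seed=int(s))
            raster = run_network(build_network(p))
            per_seed.append(feature_vector(binarize(raster)).interval_cv)
        cvs.append(float(np.mean(per_seed)))
    return np.array(gis), np.array(cvs)


def wta_transition_gi(gis, cvs) -> float:
    """Largest G_I whose CV falls below half the sweep maximum."""
    gis = np.asarray(gis)
    cvs = np.asarray(cvs)
    below = cvs < 0.5 * cvs.max()
    if not below.any():
        return float("nan")
    return float(gis[below].max())
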