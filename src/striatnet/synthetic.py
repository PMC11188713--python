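"""Synthetic inputs with known statistical structure.

Two generators support development and testing at desk scale:

* ``synth_raster`` — slice-like binary rasters from independent two-state
  Markov chains, whose stationary activity r / (1 - q + r) is known in
  closed form.  These emulate the *format* and first-order statistics of
  calcium rasters (50-400 cells, ~10 min at 250 ms bins), not any
  particular preparation.
* ``surrogate_features`` — a fast analytic stand-in for the biophysical
  simulator's (G_I, G_E) -> (activity, interval, CV) feature map.  It is a
  test double for inference-recovery studies, honoring the qualitative
  shape of the simulated feature landscape: activity falls with inhibition
  and rises with excitation, the activation interval grows with inhibition,
  and the interval CV peaks just above a winners-take-all boundary near
  G_I = 0.006 before collapsing below it (the collapse boundary rises with
  excitation).  Observation noise is Gaussian with SD equal to 5% of each
  feature's range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import CaRaster, FeatureVector
from .network import GE_MAX, GI_MAX, GI_MIN


@dataclass
class MarkovRasterSpec:
    """Independent per-cell on/off Markov chains started from stationarity."""

    n_cells: int = 200
    n_bins: int = 2400  # 10 min at 250 ms
    q: float = 0.5  # P(on -> on)
    r: float = 0.1  # P(off -> on)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.q <= 1.0 and 0.0 <= self.r <= 1.0):
            raise ValueError("q and r must lie in [0, 1]")
        if self.n_cells < 1 or self.n_bins < 1:
            raise ValueError("need at least one cell and one bin")

    @property
    def stationary_activity(self) -> float:
        denom = 1.0 - self.q + self.r
        return self.r / denom if denom > 0 else 1.0


@dataclass
class SurrogateSpec:
    """Parameters of the analytic feature map and its observation noise."""

    g_c: float = 0.006  # WTA collapse location at zero excitation offset
    noise_sd_frac: float = 0.05
    activity_range: tuple[float, float] = (0.02, 0.95)
    interval_max: float = 22.0  # bins
    cv_max: float = 4.0


def synth_raster(spec: MarkovRasterSpec) -> CaRaster:
    """Draw a binary raster of independent stationary Markov chains."""
    rng = np.random.default_rng(spec.seed)
    mat = np.zeros((spec.n_cells, spec.n_bins), dtype=np.uint8)
    state = rng.random(spec.n_cells) < spec.stationary_activity
    mat[:, 0] = state
    for b in range(1, spec.n_bins):
        p_on = np.where(state, spec.q, spec.r)
        state = rng.random(spec.n_cells) < p_on
        mat[:, b] = state
    active = np.flatnonzero(mat.any(axis=1))
    return CaRaster(matrix=mat[active], cell_indices=active,
                    n_cells_total=spec.n_cells)


def _unit(g_i: float, g_e: float) -> tuple[float, float]:
    return (g_i - GI_MIN) / (GI_MAX - GI_MIN), g_e / GE_MAX


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def surrogate_features(
    g_i: float,
    g_e: float,
    spec: SurrogateSpec = SurrogateSpec(),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> FeatureVector:
    """Noisy analytic feature map mimicking the simulated feature landscape.

    With ``rng``/``seed`` omitted the map is deterministic (zero noise).
    Raises if (g_i, g_e) falls outside the prior box.
    """
    if not (GI_MIN <= g_i <= GI_MAX and 0.0 <= g_e <= GE_MAX):
        raise ValueError("(G_I, G_E) outside the prior box")
    ui, ue = _unit(g_i, g_e)
    a_lo, a_hi = spec.activity_range
    activity = a_lo + (a_hi - a_lo) * _sigmoid(3.5 * (0.45 - ui) + 3.0 * (ue - 0.5))
    interval = spec.interval_max * (ui / (0.35 + ui)) * (1.0 + 0.35 * ue)
    # collapse boundary rises with excitation; CV peaks just above it
    g_b = spec.g_c - 0.002 + 0.002 * ue
    gate = _sigmoid((g_i - g_b) / 0.0006)
    u_b = (g_b - GI_MIN) / (GI_MAX - GI_MIN)
    bump = 1.0 + (spec.cv_max - 1.0) * np.exp(-((ui - u_b) / 0.35) ** 2)
    cv = gate * bump
    feats = np.array([activity, interval, cv])
    if rng is None and seed is not None:
        rng = np.random.default_rng(seed)
    if rng is not None:
        scale = spec.noise_sd_frac * np.array(
            [a_hi - a_lo, spec.interval_max, spec.cv_max])
        feats = feats + rng.normal(0.0, scale)
        feats = np.maximum(feats, 0.0)
    return FeatureVector(*[float(x) for x in feats])


def surrogate_dataset(
    n: int, spec: SurrogateSpec = SurrogateSpec(), seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """(theta, X): n uniform prior draws and their noisy surrogate features."""
    rng = np.random.default_rng(seed)
    theta = np.column_stack([
        rng.uniform(GI_MIN, GI_MAX, n),
        rng.uniform(0.0, GE_MAX, n),
    ])
    x = np.array([
        surrogate_features(gi, ge, spec, rng=rng).as_array()
        for gi, ge in theta
    ])
    return theta, x


def slice_like_subsample(raster: CaRaster, n_record: int, seed: int = 0) -> CaRaster:
    """Uniform random subset of recorded cells, as in a smaller field of view."""
    if n_record <= 0:
        raise ValueError("n_record must be > 0")
    if n_record > raster.n_active:
        raise ValueError("cannot record more cells than are active")
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(raster.n_active, n_record, replace=False))
    return CaRaster(
        matrix=raster.matrix[pick],
        cell_indices=raster.cell_indices[pick],
        bin_ms=raster.bin_ms,
        n_cells_total=raster.n_cells_total,
    )
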