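"""End-to-end orchestration: sweep -> features -> filter -> train -> infer.

A single config drives the whole chain.  Three named profiles trade scale
for wall time:

* ``paper`` — 400 cells, 10 min, 200 simulations, 30 training restarts:
  the full study conditions (hours of compute; not a test default).
* ``desk`` — 100 cells, 120 s, 40 simulations, 10 restarts: a desk-scale
  run preserving the pipeline shape.  At this scale rasters carry fewer,
  more active cells, so the WTA rejection threshold on the population
  fluctuation statistic (which grows as cell count falls and activity
  concentrates) is profile-scaled; the full-scale value 0.09 applies to
  the ``paper`` profile.
* ``tiny`` — a seconds-scale smoke profile for automated tests.

Every run emits a manifest (config snapshot, per-stage seeds and wall
times, artifact digests) sufficient to reproduce its outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import (binarize, feature_vector, total_fluctuation, wta_filter)
from .inference import (InferenceConfig, best_fit_lookup, posterior_map,
                        select_winner, train_restarts, weighted_mse)
from .network import (GE_MAX, GI_MAX, GI_MIN, NetworkParams, PRIOR_BOX,
                      build_network, run_network, sample_sweep)
from .synthetic import surrogate_dataset

log = logging.getLogger("striatnet")

PROFILES = {
    "paper": dict(n_cells=400, duration_s=600.0, n_sims=200, n_restarts=30,
                  holdout=20, wta_threshold=0.09, min_records=50),
    "desk": dict(n_cells=100, duration_s=120.0, n_sims=40, n_restarts=10,
                 holdout=10, wta_threshold=0.02, min_records=20),
    "tiny": dict(n_cells=30, duration_s=30.0, n_sims=12, n_restarts=2,
                 holdout=3, wta_threshold=0.0, min_records=6),
}


@dataclass
class PipelineConfig:
    profile: str = "desk"
    n_cells: int = 100
    duration_s: float = 120.0
    n_sims: int = 40
    n_restarts: int = 10
    holdout: int = 10
    wta_threshold: float = 0.02
    min_records: int = 20
    gi_range: tuple[float, float] = (GI_MIN, GI_MAX)
    ge_range: tuple[float, float] = (0.0, GE_MAX)
    transient_bins: int = 120
    surrogate: bool = False
    n_surrogate: int = 150
    n_posterior_samples: int = 10_000
    seed: int = 0
    outdir: str | None = None
    quiet: bool = False


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


def validate_config(config) -> PipelineConfig:
    """Normalize a dict or PipelineConfig; fill profile defaults; check ranges."""
    if isinstance(config, PipelineConfig):
        cfg = config
    else:
        config = dict(config)
        profile = config.pop("profile", "desk")
        if profile not in PROFILES:
            raise ConfigError(f"unknown profile '{profile}'")
        merged = dict(PROFILES[profile])
        if "seed" not in config and "seed" not in merged:
            merged["seed"] = 0
            log.info("no seed given; using deterministic default 0")
        unknown = set(config) - set(PipelineConfig.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged.update(config)
        cfg = PipelineConfig(profile=profile, **merged)
    lo, hi = cfg.gi_range
    if lo < GI_MIN or hi > GI_MAX or lo > hi:
        raise ConfigError(
            f"G_I range must lie inside the stated prior [{GI_MIN}, {GI_MAX}]")
    lo, hi = cfg.ge_range
    if lo < 0.0 or hi > GE_MAX or lo > hi:
        raise ConfigError(f"G_E range must lie inside the stated prior [0, {GE_MAX}]")
    if cfg.duration_s <= 0:
        raise ConfigError("duration must be > 0")
    if cfg.n_sims < 1:
        raise ConfigError("need at least one simulation")
    if not cfg.surrogate and cfg.holdout >= cfg.n_sims:
        raise ConfigError("holdout must be smaller than the number of records")
    return cfg


@dataclass
class RunManifest:
    config: dict
    version: str
    master_seed: int
    stage_seeds: dict
    stage_seconds: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)  # path -> sha256

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(master: int) -> dict:
    ss = np.random.SeedSequence(master)
    names = ("sweep", "simulate", "train", "infer")
    return {n: int(s.generate_state(1)[0] % (2**31 - 1))
            for n, s in zip(names, ss.spawn(len(names)))}


def simulate_record(gi, ge, n_cells, duration_s, seed, transient_bins):
    """One sweep point: network run -> calcium raster -> features + QC."""
    npar = NetworkParams(n_cells=n_cells, g_i=float(gi), g_e=float(ge),
                         duration_s=duration_s, seed=int(seed))
    raster = run_network(build_network(npar))
    ca = binarize(raster)
    fv = feature_vector(ca)
    n_bins = ca.n_bins
    tb = transient_bins if n_bins - transient_bins >= 10 else max(0, n_bins // 4)
    qc = total_fluctuation(ca, transient_bins=tb)
    return (np.array([gi, ge]), fv, qc), ca


def run_pipeline(config, target_features=None):
    """Execute the full chain; returns (RunManifest, results dict).

    ``target_features`` — optional list of feature vectors (e.g. from slice
    rasters) to infer on; defaults to the winner's held-out simulations.
    """
    cfg = validate_config(config)
    if cfg.quiet:
        log.setLevel(logging.WARNING)
    seeds = _stage_seeds(cfg.seed)
    manifest = RunManifest(config=asdict(cfg), version=__version__,
                           master_seed=cfg.seed, stage_seeds=seeds)
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    results = {}

    def stage(name):
        t0 = time.time()
        log.info("stage %s: start", name)
        return lambda: manifest.stage_seconds.__setitem__(
            name, round(time.time() - t0, 3))

    # -- sweep + simulate (or surrogate) ------------------------------
    done = stage("simulate")
    try:
        if cfg.surrogate:
            theta, x = surrogate_dataset(cfg.n_surrogate, seed=seeds["sweep"])
            records = (theta, x)
            kept_records, removed = records, []
            features_df = pd.DataFrame(
                np.column_stack([theta, x]),
                columns=["g_i", "g_e", "activity", "interval", "interval_cv"])
        else:
            pairs = sample_sweep(cfg.n_sims,
                                 (cfg.gi_range, cfg.ge_range), seeds["sweep"])
            sim_seeds = np.random.SeedSequence(seeds["simulate"]).spawn(cfg.n_sims)
            recs = []
            for i, (gi, ge) in enumerate(pairs):
                s = int(sim_seeds[i].generate_state(1)[0] % (2**31 - 1))
                rec, _ = simulate_record(gi, ge, cfg.n_cells, cfg.duration_s,
                                         s, cfg.transient_bins)
                recs.append(rec)
                log.info("sim %d/%d G_I=%.4g G_E=%.3g fluct=%.3f",
                         i + 1, cfg.n_sims, gi, ge, rec[2].total_fluctuation)
            kept_records, removed = wta_filter(recs, cfg.wta_threshold)
            records = recs
            features_df = pd.DataFrame(
                [dict(sim_id=i, g_i=r[0][0], g_e=r[0][1],
                      activity=r[1].activity, interval=r[1].interval,
                      interval_cv=r[1].interval_cv,
                      fluct=r[2].total_fluctuation,
                      kept=r[2].total_fluctuation >= cfg.wta_threshold)
                 for i, r in enumerate(recs)])
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e
    done()
    if outdir is not None:
        p = outdir / "features.tsv"
        features_df.to_csv(p, sep="\t", index=False)
        manifest.artifacts[str(p)] = _digest(p)
    results["features"] = features_df
    n_kept = (len(kept_records) if isinstance(kept_records, list)
              else kept_records[0].shape[0])
    if n_kept < cfg.min_records:
        raise StageError(
            "filter",
            RuntimeError(f"only {n_kept} records pass the WTA filter "
                         f"(min_records = {cfg.min_records})"))
    results["n_kept"] = n_kept

    # -- train ---------------------------------------------------------
    done = stage("train")
    try:
        icfg = InferenceConfig(n_restarts=cfg.n_restarts, holdout=cfg.holdout,
                               seed=seeds["train"],
                               n_samples=cfg.n_posterior_samples)
        restarts = train_restarts(kept_records, icfg, seed=seeds["train"])
        winner = select_winner(restarts)
    except Exception as e:  # noqa: BLE001
        raise StageError("train", e) from e
    done()
    results["winner"] = winner
    results["restart_mses"] = [r.holdout_mse for r in restarts]
    if outdir is not None:
        p = outdir / "estimator.json"
        winner.estimator.save(p)
        manifest.artifacts[str(p)] = _digest(p)

    # -- infer + best fit ----------------------------------------------
    done = stage("infer")
    try:
        theta_all, x_all = (kept_records if isinstance(kept_records, tuple)
                            else _split(kept_records))
        if target_features is None:
            idx = winner.holdout_idx
            targets = [x_all[i] for i in idx[: min(5, idx.size)]]
        else:
            targets = [t.as_array() if hasattr(t, "as_array") else np.asarray(t)
                       for t in target_features]
        rng = np.random.default_rng(seeds["infer"])
        posteriors, best_fits = [], []
        for tx in targets:
            summ = posterior_map(winner.estimator, tx, icfg,
                                 n_samples=cfg.n_posterior_samples, rng=rng)
            posteriors.append(summ)
            i_best, _ = best_fit_lookup(summ.map_params, (theta_all, x_all))
            best_fits.append((i_best, tuple(theta_all[i_best])))
    except Exception as e:  # noqa: BLE001
        raise StageError("infer", e) from e
    done()
    results["posteriors"] = posteriors
    results["best_fits"] = best_fits
    if outdir is not None:
        p = outdir / "posteriors.tsv"
        pd.DataFrame(
            [dict(target=i, map_gi=s.map_gi, map_ge=s.map_ge,
                  marg_peak_gi=s.marginal_peak_gi, marg_peak_ge=s.marginal_peak_ge,
                  best_fit_sim=bf[0])
             for i, (s, bf) in enumerate(zip(posteriors, best_fits))]
        ).to_csv(p, sep="\t", index=False)
        manifest.artifacts[str(p)] = _digest(p)
        mp = outdir / "manifest.json"
        manifest.save(mp)
    return manifest, results


def _split(records):
    theta = np.array([r[0] for r in records])
    x = np.array([r[1].as_array() for r in records])
    return theta, x
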