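"""Experiment orchestration: ensembles of episodes across domain sizes.

Ties the pipeline stages together: seeded initial conditions, episode
simulation with spiral counting, per-size escape-rate fits, and the
across-size supertransient scaling fit.  Runs are resumable through the
manifest: episodes already recorded are skipped; per-episode failures
are recorded and do not abort the experiment.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .config import ExperimentConfig, RunManifest, stage_seed
from .grid import Grid
from .initial_conditions import ProtocolKnobs, make_initial_condition
from .integrator import NumericsConfig, run_episode
from .io import write_results_json, write_series_csv, write_snapshot
from .models.bocf import load_bocf_params
from .models.tnnp import load_tnnp_params
from .phase import SpiralCounter
from .records import TERMINATED
from .transients import fit_escape_rate, fit_supertransient_scaling

log = logging.getLogger("spiralchaos")

__all__ = ["run_experiment", "load_model"]


def load_model(config: ExperimentConfig):
    """(params, NumericsConfig) for the configured model."""
    if config.model == "bocf":
        params = load_bocf_params(config.parameter_set)
        cfg = NumericsConfig.bocf_defaults()
    else:
        params = load_tnnp_params(config.parameter_set)
        cfg = NumericsConfig.tnnp_defaults()
    if config.h is not None or config.dt is not None:
        cfg = NumericsConfig(dt=config.dt if config.dt is not None else cfg.dt,
                             h=config.h if config.h is not None else cfg.h)
    return params, cfg


def run_experiment(config: ExperimentConfig) -> RunManifest:
    """Run (or resume) the configured experiment; returns the manifest.

    Output layout under ``config.output_root``:
    manifest.csv, results.json, series/<episode_id>.csv and optionally
    snapshots/<episode_id>.h5.
    """
    root = Path(config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(root / "manifest.csv", config)
    params, cfg = load_model(config)
    knobs = ProtocolKnobs(min_spirals=config.min_spirals,
                          settle_time=config.settle_time)

    for L in config.domain_lengths:
        grid = Grid.square(L, cfg.h)
        for k in range(config.ensemble_size):
            episode_id = f"{config.model}_L{L:g}_e{k:03d}"
            if manifest.has_episode(episode_id):
                log.info("skip %s (already in manifest)", episode_id)
                continue
            seed = stage_seed(config.base_seed, f"ic_L{L:g}", k)
            log.info("episode %s: seed %d", episode_id, seed)
            try:
                state, info = make_initial_condition(
                    grid, params, cfg, seed, knobs, model=config.model,
                    return_info=True)
            except RuntimeError as exc:
                log.warning("episode %s: IC failed: %s", episode_id, exc)
                manifest.append({"episode_id": episode_id, "seed": seed,
                                 "L_mm": L, "A_mm2": grid.area,
                                 "lifetime_s": np.nan, "status": "ic_failed",
                                 "n_spiral_initial": 0, "series_path": "",
                                 "snapshot_path": ""})
                continue
            snap_path = ""
            if config.write_snapshots:
                snap_path = str(root / "snapshots" / f"{episode_id}.h5")
                write_snapshot(snap_path, state, config=config.to_dict())
            counter = SpiralCounter()
            rec = run_episode(state, params, cfg, t_max=config.t_max,
                              observers=[counter],
                              sample_interval=config.sample_interval,
                              confirm_window=config.confirm_window)
            t, counts = counter.series()
            series_path = root / "series" / f"{episode_id}.csv"
            write_series_csv(series_path, t, counts)
            manifest.append({
                "episode_id": episode_id, "seed": seed, "L_mm": L,
                "A_mm2": grid.area, "lifetime_s": rec.lifetime,
                "status": rec.status, "n_spiral_initial": info["n_spiral"],
                "series_path": str(series_path), "snapshot_path": snap_path,
            })
            log.info("episode %s: %s, lifetime %.3f s", episode_id,
                     rec.status, rec.lifetime)

    _write_results(root, config, manifest)
    return manifest


def _write_results(root: Path, config: ExperimentConfig,
                   manifest: RunManifest):
    df = manifest.episodes()
    results: Dict = {"config": config.to_dict(),
                     "config_hash": config.config_hash(),
                     "per_size": {}}
    areas, mean_lifetimes = [], []
    for L, sub in df.groupby("L_mm"):
        ok = sub[sub["status"].isin([TERMINATED, "censored"])]
        entry: Dict = {"n_episodes": int(len(sub)),
                       "n_terminated": int((sub["status"] == TERMINATED).sum())}
        term = sub[sub["status"] == TERMINATED]
        if len(term):
            entry["mean_lifetime_s"] = float(term["lifetime_s"].mean())
        if len(ok) >= 10:  # escape-rate fit needs a usable curve
            pairs = list(zip(ok["lifetime_s"], ok["status"]))
            try:
                fit = fit_escape_rate(pairs, config.fit_threshold_fraction)
                entry.update(kappa_per_s=fit.kappa_,
                             kappa_sd=fit.kappa_sd_,
                             avg_lifetime_s=fit.avg_lifetime_)
            except (ValueError, RuntimeError) as exc:
                entry["escape_fit_error"] = str(exc)
        results["per_size"][f"{L:g}"] = entry
        if len(term):
            areas.append(float(sub["A_mm2"].iloc[0]))
            mean_lifetimes.append(float(term["lifetime_s"].mean()))
    if len(areas) >= 3 and all(T > 1.0 for T in mean_lifetimes):
        fit = fit_supertransient_scaling(areas, mean_lifetimes)
        results["scaling"] = {"a_tilde_per_mm2": fit.a_tilde_,
                              "gamma": fit.gamma_,
                              "a_tilde_sd": fit.a_tilde_sd_,
                              "gamma_sd": fit.gamma_sd_}
    write_results_json(root / "results.json", results)
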