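"""End-to-end orchestration: simulate all cells, run every analysis, write
tables and a manifest.

Stages: (1) stochastic simulation of all (condition, coherence) cells;
(2) behavioral analysis -- psychometric fits, chronometric tables and the
threshold-compensation sweep; (3) noise-free phase-plane portraits per cell;
(4) ideal-observer analysis. All outputs are CSV/JSON under one directory;
the manifest records the config hash, seed and file list, so a run is fully
reproducible from its output directory.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (chronometric_summary, compensation_summary,
                       fit_condition_psychometric, threshold_sweep,
                       PsychometricFitError)
from .config import ExperimentConfig
from .observer import discrimination_summary, last_intersection_summary
from .phase import compute_phase_portrait
from .simulate import (SimulationResult, baseline_difference, run_batch,
                       trial_averaged_traces)

__all__ = ["run_study", "save_result", "load_result"]

logger = logging.getLogger(__name__)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def save_result(result: SimulationResult, out_dir: str | Path) -> None:
    """Persist records (CSV) and full traces (NPZ) for later analysis."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(out / "records.csv", index=False)
    arrays: dict[str, np.ndarray] = {}
    meta = {"cells": [], "theta": result.theta,
            "master_seed": result.master_seed, "trace_dt": result.trace_dt,
            "coherences": list(result.coherences),
            "conditions": [{"name": c.name, "I0": c.I0,
                            "sigma_noise": c.sigma_noise}
                           for c in result.conditions],
            "schedule": {"t_prestim": result.schedule.t_prestim,
                         "t_stim": result.schedule.t_stim,
                         "dt": result.schedule.dt}}
    for i, ((cond, c), tr) in enumerate(sorted(result.traces.items())):
        arrays[f"time_{i}"] = tr.time_ms
        arrays[f"rt_{i}"] = tr.r_target
        arrays[f"rd_{i}"] = tr.r_distractor
        arrays[f"send_{i}"] = tr.S_end
        meta["cells"].append({"index": i, "condition": cond, "coherence": c})
    np.savez_compressed(out / "traces.npz", **arrays)
    _write_json(out / "simulation_meta.json", meta)


def load_result(out_dir: str | Path,
                config: ExperimentConfig | None = None) -> SimulationResult:
    """Reload a persisted simulation (records + traces)."""
    from .params import ConditionSpec, EpochSchedule, ModelParameters
    from .simulate import CellTraces

    out = Path(out_dir)
    meta = json.loads((out / "simulation_meta.json").read_text())
    records = pd.read_csv(out / "records.csv")
    # object columns with None round-trip through CSV as NaN; normalize
    records["correct"] = records.correct.map(
        {True: True, False: False, "True": True, "False": False}).where(
        records.correct.notna(), None)
    data = np.load(out / "traces.npz")
    traces = {}
    for cell in meta["cells"]:
        i = cell["index"]
        traces[(cell["condition"], cell["coherence"])] = CellTraces(
            cell["condition"], cell["coherence"], data[f"time_{i}"],
            data[f"rt_{i}"], data[f"rd_{i}"], data[f"send_{i}"])
    params = config.params if config else ModelParameters()
    sched = EpochSchedule(**meta["schedule"])
    conds = tuple(ConditionSpec(c["name"], c["I0"], c["sigma_noise"])
                  for c in meta["conditions"])
    return SimulationResult(records, traces, params, conds,
                            tuple(meta["coherences"]), sched, meta["theta"],
                            meta["master_seed"], meta["trace_dt"])


def run_study(config: ExperimentConfig, out_dir: str | Path,
              n_trials: int | None = None,
              master_seed: int | None = None,
              save_traces: bool = False) -> dict:
    """Run the full study and write all figure-level tables.

    Returns the manifest dictionary. ``n_trials``/``master_seed`` override
    the config (convenient for smoke runs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = n_trials if n_trials is not None else config.n_trials
    seed = master_seed if master_seed is not None else config.master_seed
    stage_times: dict[str, float] = {}

    t0 = time.perf_counter()
    logger.info("stage simulate: %d conditions x %d coherences x %d trials",
                len(config.conditions), len(config.coherences), n)
    try:
        result = run_batch(config.conditions, config.coherences, n,
                           config.schedule, config.theta, config.params,
                           seed, config.sustain_steps, config.trace_dt)
    except Exception:
        logger.exception("stage simulate failed (master seed %d)", seed)
        raise
    stage_times["simulate"] = time.perf_counter() - t0
    result.records.to_csv(out / "records.csv", index=False)
    if save_traces:
        save_result(result, out)

    avg_rows = []
    for (cond, c) in sorted(result.traces):
        try:
            df = trial_averaged_traces(result, cond, c)
        except ValueError:
            continue
        df.insert(0, "condition", cond)
        df.insert(1, "coherence", c)
        avg_rows.append(df)
    pd.concat(avg_rows, ignore_index=True).to_csv(
        out / "trial_averaged_traces.csv", index=False)

    # --- behavior ---
    t0 = time.perf_counter()
    recs = result.records
    deltas = {}
    by_name = {c.name: c for c in config.conditions}
    if {"speed", "neutral"} <= set(by_name):
        deltas["delta_ns"] = baseline_difference(
            recs[recs.condition == "speed"],
            recs[recs.condition == "neutral"])
    if {"neutral", "accuracy"} <= set(by_name):
        deltas["delta_na"] = baseline_difference(
            recs[recs.condition == "neutral"],
            recs[recs.condition == "accuracy"])
    psycho = {}
    for cond in by_name:
        try:
            fit = fit_condition_psychometric(recs, cond)
            psycho[cond] = {"alpha": fit.alpha, "beta": fit.beta,
                            "c75": fit.c75,
                            "log_likelihood": fit.log_likelihood}
        except PsychometricFitError as err:
            logger.warning("psychometric fit failed for %s: %s", cond, err)
            psycho[cond] = {"error": str(err)}
    _write_json(out / "psychometric_fits.json",
                {"fits": psycho, "baseline_differences_hz": deltas})
    chronometric_summary(recs).to_csv(out / "chronometric.csv", index=False)
    sweep = threshold_sweep(result, config.theta_grid,
                            deltas.get("delta_ns"), deltas.get("delta_na"),
                            config.probe_coherences, config.sustain_steps)
    sweep.to_csv(out / "threshold_sweep.csv", index=False)
    comp_measures = ["c75"] + [f"dt_c{c:g}" for c in config.probe_coherences]
    compensation_summary(sweep, comp_measures).to_csv(
        out / "compensation.csv", index=False)
    stage_times["behavior"] = time.perf_counter() - t0

    # --- phase plane ---
    t0 = time.perf_counter()
    phase_rows = []
    for cond in config.conditions:
        S0 = result.mean_initial_state(cond.name)
        for c in config.coherences:
            try:
                portrait = compute_phase_portrait(config.params, cond, c,
                                                  stim_on=True,
                                                  initial_state_S=S0)
            except Exception:
                logger.exception("stage phase failed (%s, c=%g)",
                                 cond.name, c)
                raise
            row = {"condition": cond.name, "coherence": c,
                   "n_fixed_points": len(portrait.fixed_points),
                   "tau_eff_ms": portrait.tau_eff,
                   "init_distance_hz": portrait.init_distance,
                   "initial_rate_target_hz": portrait.initial_state_rates[0],
                   "initial_rate_distractor_hz":
                       portrait.initial_state_rates[1]}
            if portrait.saddle is not None:
                row.update(saddle_S1=portrait.saddle.S[0],
                           saddle_S2=portrait.saddle.S[1],
                           saddle_r1_hz=portrait.saddle.rates[0],
                           saddle_r2_hz=portrait.saddle.rates[1])
            phase_rows.append(row)
    pd.DataFrame(phase_rows).to_csv(out / "phase_portraits.csv", index=False)
    stage_times["phase"] = time.perf_counter() - t0

    # --- observer ---
    t0 = time.perf_counter()
    per_cell, pooled = discrimination_summary(result,
                                              config.observer_criterion,
                                              config.observer_sustain_bins)
    per_cell.to_csv(out / "observer_cells.csv", index=False)
    pooled.to_csv(out / "observer_pooled.csv", index=False)
    last_intersection_summary(result, config.observer_smooth_ms).to_csv(
        out / "last_intersection.csv", index=False)
    stage_times["observer"] = time.perf_counter() - t0

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash,
        "master_seed": seed,
        "n_trials": n,
        "coherences": list(config.coherences),
        "conditions": sorted(by_name),
        "outputs": sorted(p.name for p in out.iterdir()
                          if p.name != "manifest.json"),
    }
    _write_json(out / "manifest.json", manifest)
    for stage, dt in stage_times.items():
        logger.info("stage %s: %.1f s", stage, dt)
    return manifest
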