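"""Experiment configuration: a flat YAML file validated on load.

Unknown keys are rejected so typos cannot silently fall back to defaults.
The canonical default configuration ships with the package
(``satnet/data/default.yaml``) and is printed by ``satnet params``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .params import ConditionSpec, EpochSchedule, ModelParameters

__all__ = ["ExperimentConfig", "load_config", "default_config_text",
           "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class ExperimentConfig:
    """Validated study configuration."""

    params: ModelParameters
    conditions: tuple[ConditionSpec, ...]
    schedule: EpochSchedule
    coherences: tuple[float, ...]
    n_trials: int
    theta: float
    sustain_steps: int
    trace_dt: float
    master_seed: int
    theta_grid: tuple[float, ...]
    probe_coherences: tuple[float, ...]
    observer_criterion: float
    observer_sustain_bins: int
    observer_smooth_ms: float
    raw: dict = field(repr=False, default_factory=dict)

    def condition(self, name: str) -> ConditionSpec:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def default_config_text() -> str:
    """The shipped canonical configuration, verbatim YAML."""
    return (resources.files("satnet") / "data" / "default.yaml").read_text()


def _take(mapping: dict, section: str, allowed: set[str]) -> dict:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}': {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")
    return mapping


def _build(doc: dict) -> ExperimentConfig:
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    _take(doc, "<root>", {"model", "conditions", "schedule", "experiment",
                          "threshold_sweep", "observer"})

    m = _take(doc.get("model", {}), "model",
              {"a_hz_per_na", "b_hz", "d_s", "gamma", "tau_s_ms",
               "tau_noise_ms", "j_self_na", "j_cross_na", "j_ext_na_per_hz",
               "mu0_hz"})
    base = ModelParameters(
        a=m.get("a_hz_per_na", 270.0), b=m.get("b_hz", 108.0),
        d=m.get("d_s", 0.154), gamma=m.get("gamma", 0.641),
        tau_S=m.get("tau_s_ms", 100.0), tau_noise=m.get("tau_noise_ms", 2.0),
        J_self=m.get("j_self_na", 0.2609), J_cross=m.get("j_cross_na", 0.0497),
        J_ext=m.get("j_ext_na_per_hz", 5.2e-4), mu0=m.get("mu0_hz", 30.0))

    conds = []
    cond_doc = doc.get("conditions", {})
    if not cond_doc:
        raise ConfigError("at least one condition is required")
    for name in ("speed", "neutral", "accuracy"):
        if name in cond_doc:
            cd = _take(cond_doc[name], f"conditions.{name}",
                       {"i0_pa", "sigma_noise_na"})
            conds.append(ConditionSpec(
                name, float(cd["i0_pa"]) / 1000.0,  # pA -> nA
                float(cd.get("sigma_noise_na", 0.02))))
    extra = set(cond_doc) - {"speed", "neutral", "accuracy"}
    for name in sorted(extra):
        cd = _take(cond_doc[name], f"conditions.{name}",
                   {"i0_pa", "sigma_noise_na"})
        conds.append(ConditionSpec(name, float(cd["i0_pa"]) / 1000.0,
                                   float(cd.get("sigma_noise_na", 0.02))))
    named = {c.name: c for c in conds}
    if {"speed", "neutral", "accuracy"} <= set(named):
        if not (named["accuracy"].I0 < named["neutral"].I0
                < named["speed"].I0):
            raise ConfigError(
                "condition currents must satisfy "
                "I0(accuracy) < I0(neutral) < I0(speed)")

    s = _take(doc.get("schedule", {}), "schedule",
              {"t_prestim_ms", "t_stim_ms", "dt_ms"})
    sched = EpochSchedule(t_prestim=s.get("t_prestim_ms", 2500.0),
                          t_stim=s.get("t_stim_ms", 5000.0),
                          dt=s.get("dt_ms", 0.1))

    e = _take(doc.get("experiment", {}), "experiment",
              {"coherences_pct", "n_trials", "theta_hz", "sustain_steps",
               "trace_dt_ms", "master_seed"})
    coherences = tuple(float(c) for c in
                       e.get("coherences_pct", (0, 1, 2, 4, 8, 16, 32)))
    if any(not 0 <= c <= 100 for c in coherences):
        raise ConfigError("coherences must lie in [0, 100] percent")

    t = _take(doc.get("threshold_sweep", {}), "threshold_sweep",
              {"grid_min_hz", "grid_max_hz", "step_hz",
               "probe_coherences_pct"})
    lo = float(t.get("grid_min_hz", 9.0))
    hi = float(t.get("grid_max_hz", 21.0))
    step = float(t.get("step_hz", 1.0))
    grid = tuple(np.round(np.arange(lo, hi + step / 2, step), 9))

    o = _take(doc.get("observer", {}), "observer",
              {"criterion", "sustain_bins", "smooth_ms"})

    return ExperimentConfig(
        params=base, conditions=tuple(conds), schedule=sched,
        coherences=coherences,
        n_trials=int(e.get("n_trials", 1000)),
        theta=float(e.get("theta_hz", 15.0)),
        sustain_steps=int(e.get("sustain_steps", 1)),
        trace_dt=float(e.get("trace_dt_ms", 10.0)),
        master_seed=int(e.get("master_seed", 12345)),
        theta_grid=grid,
        probe_coherences=tuple(float(c) for c in
                               t.get("probe_coherences_pct", (1, 32))),
        observer_criterion=float(o.get("criterion", 0.75)),
        observer_sustain_bins=int(o.get("sustain_bins", 3)),
        observer_smooth_ms=float(o.get("smooth_ms", 50.0)),
        raw=doc)


def load_config(path: str | Path | None = None) -> ExperimentConfig:
    """Load and validate a YAML config; the shipped default if path is None."""
    text = default_config_text() if path is None else Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse configuration: {err}") from err
    try:
        return _build(doc)
    except (TypeError, KeyError, ValueError) as err:
        if isinstance(err, ConfigError):
            raise
        raise ConfigError(str(err)) from err
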