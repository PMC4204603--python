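"""Stochastic trial simulation of the 2-choice random-dot-motion task.

Each trial integrates the two gating variables with Euler-Maruyama at step
``dt`` through a pre-stimulus epoch and a stimulus epoch, with independent
Ornstein-Uhlenbeck noise currents to the two populations. Population rates
``r_i = H(x_i)`` (noise included) are monitored every step; the first
crossing of the choice threshold ``theta`` by either population during the
stimulus epoch registers the choice and the decision time. Integration
continues to stimulus end regardless, so full-length rate traces are
available for threshold re-detection and ideal-observer analyses.

Trials are vectorized across a (condition, coherence) cell, but every trial
consumes its own seeded random stream, so single trials are bit-reproducible
in isolation (``run_trial`` is exact on the batch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import transfer_rate
from .noise import ou_coefficients, trial_generator
from .params import (DEFAULT_THETA, ConditionSpec, EpochSchedule,
                     ModelParameters, NoiseSpec)

__all__ = [
    "TrialRecord",
    "CellTraces",
    "SimulationResult",
    "run_trial",
    "run_batch",
    "detect_choice",
    "baseline_difference",
    "trial_averaged_traces",
]

logger = logging.getLogger(__name__)

#: Length of the pre-stimulus window over which baseline rates are averaged, ms.
BASELINE_WINDOW_MS = 1000.0

#: Initial gating value at trial start (relaxes to the spontaneous state
#: during the 2.5 s pre-stimulus epoch).
S_INIT = 0.1

# RNG draws are chunked in time; chunk size only affects memory, not streams.
_CHUNK_STEPS = 4000

CHOICE_TARGET = "target"
CHOICE_DISTRACTOR = "distractor"
CHOICE_UNDECIDED = "undecided"


@dataclass
class TrialRecord:
    """Outcome of one simulated decision trial."""

    condition: str
    coherence: float
    trial_index: int
    seed_key: tuple[int, int, int, int]
    choice: str
    decision_time: float | None  # ms from stimulus onset; None if undecided
    correct: bool | None  # None if undecided; at c=0, correct := chose target
    baseline_rate: float  # Hz, mean over last 1000 ms of pre-stimulus


@dataclass
class CellTraces:
    """Per-trial rate traces for one (condition, coherence) cell.

    ``time_ms`` is aligned to stimulus onset at t = 0 (pre-stimulus times are
    negative). Rates are instantaneous samples at the output resolution.
    ``S_end`` holds each trial's gating state at the end of the pre-stimulus
    epoch.
    """

    condition: str
    coherence: float
    time_ms: np.ndarray  # (n_bins,)
    r_target: np.ndarray  # (n_trials, n_bins) float32
    r_distractor: np.ndarray  # (n_trials, n_bins) float32
    S_end: np.ndarray  # (n_trials, 2)

    @property
    def stim_mask(self) -> np.ndarray:
        return self.time_ms >= 0.0


@dataclass
class SimulationResult:
    """Records plus traces for a batch of cells, with the run's settings."""

    records: pd.DataFrame
    traces: dict[tuple[str, float], CellTraces]
    params: ModelParameters
    conditions: tuple[ConditionSpec, ...]
    coherences: tuple[float, ...]
    schedule: EpochSchedule
    theta: float
    master_seed: int
    trace_dt: float

    def cell_records(self, condition: str, coherence: float) -> pd.DataFrame:
        r = self.records
        return r[(r.condition == condition) & (r.coherence == coherence)]

    def mean_initial_state(self, condition: str,
                           coherence: float | None = None) -> np.ndarray:
        """Mean gating state (S1, S2) at the end of the pre-stimulus epoch."""
        keys = [k for k in self.traces
                if k[0] == condition and (coherence is None or k[1] == coherence)]
        if not keys:
            raise KeyError(f"no traces stored for condition {condition!r}")
        return np.mean(np.vstack([self.traces[k].S_end for k in keys]), axis=0)

    def mean_baseline_rate(self, condition: str) -> float:
        """Across-trial mean baseline rate of a condition, Hz."""
        sub = self.records[self.records.condition == condition]
        if sub.empty:
            raise ValueError(f"no records for condition {condition!r}")
        return float(sub.baseline_rate.mean())


def _simulate_cell(params: ModelParameters, cond: ConditionSpec, c: float,
                   sched: EpochSchedule, theta: float, n_trials: int,
                   master_seed: int, cond_index: int, coh_index: int,
                   sustain_steps: int = 1, trace_dt: float = 10.0,
                   trial_indices=None) -> tuple[list[TrialRecord], CellTraces]:
    """Vectorized Euler-Maruyama integration of one cell's trials."""
    p = params.with_condition(cond)
    spec = NoiseSpec(sigma=p.sigma_noise, tau=p.tau_noise)
    dec, amp = ou_coefficients(sched.dt, spec)
    dt = sched.dt
    n_pre, n_tot = sched.n_prestim, sched.n_total
    n_base = int(round(BASELINE_WINDOW_MS / dt))
    stride = int(round(trace_dt / dt))
    if abs(stride * dt - trace_dt) > 1e-9 or stride < 1:
        raise ValueError("trace_dt must be a positive multiple of dt")
    n_bins = (n_tot + stride - 1) // stride

    if trial_indices is None:
        trial_indices = list(range(n_trials))
    n_trials = len(trial_indices)
    gens = [trial_generator(master_seed, cond_index, coh_index, j)
            for j in trial_indices]

    S1 = np.full(n_trials, S_INIT)
    S2 = np.full(n_trials, S_INIT)
    init = np.stack([g.normal(0.0, spec.sigma, 2) for g in gens])
    In1, In2 = init[:, 0].copy(), init[:, 1].copy()

    Is1 = p.J_ext * p.mu0 * (1.0 + c / 100.0)
    Is2 = p.J_ext * p.mu0 * (1.0 - c / 100.0)
    g_gate = p.gamma * 1e-3
    inv_tauS = 1.0 / p.tau_S

    r_t = np.empty((n_trials, n_bins), dtype=np.float32)
    r_d = np.empty((n_trials, n_bins), dtype=np.float32)
    S_end = np.empty((n_trials, 2))
    bl_sum = np.zeros(n_trials)
    dtime = np.full(n_trials, np.nan)
    choice = np.zeros(n_trials, dtype=np.int8)  # 0 undecided, 1 target, 2 dist
    above1 = np.zeros(n_trials, dtype=np.int32)
    above2 = np.zeros(n_trials, dtype=np.int32)

    step = 0
    bin_idx = 0
    for t0 in range(0, n_tot, _CHUNK_STEPS):
        m = min(_CHUNK_STEPS, n_tot - t0)
        xi = np.empty((m, 2, n_trials))
        for j, gen in enumerate(gens):
            xi[:, :, j] = gen.standard_normal((m, 2))
        for i in range(m):
            if step == n_pre:
                S_end[:, 0] = S1
                S_end[:, 1] = S2
            In1 *= 1.0 - dec
            In1 += amp * xi[i, 0]
            In2 *= 1.0 - dec
            In2 += amp * xi[i, 1]
            stim = step >= n_pre
            x1 = p.J_self * S1 - p.J_cross * S2 + p.I0 + In1
            x2 = p.J_self * S2 - p.J_cross * S1 + p.I0 + In2
            if stim:
                x1 += Is1
                x2 += Is2
            r1 = transfer_rate(x1, p)
            r2 = transfer_rate(x2, p)
            if step % stride == 0:
                r_t[:, bin_idx] = r1
                r_d[:, bin_idx] = r2
                bin_idx += 1
            if n_pre - n_base <= step < n_pre:
                bl_sum += 0.5 * (r1 + r2)
            if stim:
                above1[:] = np.where(r1 >= theta, above1 + 1, 0)
                above2[:] = np.where(r2 >= theta, above2 + 1, 0)
                und = choice == 0
                win1 = und & (above1 >= sustain_steps)
                win2 = und & (above2 >= sustain_steps) & ~win1
                if win1.any() or win2.any():
                    t_now = (step - n_pre + 1) * dt
                    choice[win1] = 1
                    dtime[win1] = t_now
                    choice[win2] = 2
                    dtime[win2] = t_now
            S1 += dt * (-S1 * inv_tauS + (1.0 - S1) * g_gate * r1)
            S2 += dt * (-S2 * inv_tauS + (1.0 - S2) * g_gate * r2)
            np.clip(S1, 0.0, 1.0, out=S1)
            np.clip(S2, 0.0, 1.0, out=S2)
            step += 1
    if not (np.isfinite(S1).all() and np.isfinite(S2).all()):
        bad = int(np.flatnonzero(~np.isfinite(S1 + S2))[0])
        raise FloatingPointError(
            f"non-finite state in trial with seed key "
            f"{(master_seed, cond_index, coh_index, bad)}")

    time_ms = -sched.t_prestim + np.arange(n_bins) * trace_dt
    baseline = bl_sum / n_base
    records = []
    for j, tj in enumerate(trial_indices):
        ch = (CHOICE_UNDECIDED, CHOICE_TARGET, CHOICE_DISTRACTOR)[choice[j]]
        correct = None if choice[j] == 0 else bool(choice[j] == 1)
        records.append(TrialRecord(
            condition=cond.name, coherence=c, trial_index=tj,
            seed_key=(master_seed, cond_index, coh_index, tj), choice=ch,
            decision_time=float(dtime[j]) if choice[j] else None,
            correct=correct, baseline_rate=float(baseline[j])))
    traces = CellTraces(cond.name, c, time_ms, r_t, r_d, S_end)
    return records, traces


def run_trial(cond: ConditionSpec, c: float, sched: EpochSchedule,
              theta: float = DEFAULT_THETA,
              params: ModelParameters = ModelParameters(),
              master_seed: int = 0, cond_index: int = 0, coh_index: int = 0,
              trial_index: int = 0, sustain_steps: int = 1,
              trace_dt: float = 10.0) -> tuple[TrialRecord, CellTraces]:
    """Simulate a single trial (bit-identical to its slot in a batch)."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    recs, traces = _simulate_cell(params, cond, c, sched, theta, 1,
                                  master_seed, cond_index, coh_index,
                                  sustain_steps, trace_dt,
                                  trial_indices=[trial_index])
    return recs[0], traces


def run_batch(conditions, coherences, n_trials: int, sched: EpochSchedule,
              theta: float = DEFAULT_THETA,
              params: ModelParameters = ModelParameters(),
              master_seed: int = 0, sustain_steps: int = 1,
              trace_dt: float = 10.0) -> SimulationResult:
    """Simulate ``n_trials`` per (condition, coherence) cell.

    Returns all trial records plus per-cell rate traces sampled at
    ``trace_dt`` ms.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be positive")
    conditions = tuple(conditions)
    coherences = tuple(float(c) for c in coherences)
    all_records: list[TrialRecord] = []
    traces: dict[tuple[str, float], CellTraces] = {}
    for ci, cond in enumerate(conditions):
        for ki, c in enumerate(coherences):
            recs, tr = _simulate_cell(params, cond, c, sched, theta, n_trials,
                                      master_seed, ci, ki, sustain_steps,
                                      trace_dt)
            n_undec = sum(r.choice == CHOICE_UNDECIDED for r in recs)
            logger.info("cell %s c=%g%%: %d trials, %d undecided",
                        cond.name, c, n_trials, n_undec)
            all_records.extend(recs)
            traces[(cond.name, c)] = tr
    df = pd.DataFrame([{
        "condition": r.condition, "coherence": r.coherence,
        "trial_index": r.trial_index, "seed_key": str(r.seed_key),
        "choice": r.choice, "decision_time": r.decision_time,
        "correct": r.correct, "baseline_rate": r.baseline_rate,
    } for r in all_records])
    return SimulationResult(df, traces, params, conditions, coherences,
                            sched, theta, master_seed, trace_dt)


def detect_choice(time_ms: np.ndarray, r_target: np.ndarray,
                  r_distractor: np.ndarray, theta: float,
                  sustain_bins: int = 1) -> tuple[str, float | None]:
    """First-crossing choice detection on a pair of rate traces.

    Only samples with ``time_ms >= 0`` (stimulus epoch) are considered. The
    population whose rate first reaches ``theta`` (sustained for
    ``sustain_bins`` consecutive samples) wins; a tie at the same sample goes
    to the higher rate (then to the target). Returns
    ``("undecided", None)`` if neither crosses.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    rt = np.asarray(r_target, dtype=float)
    rd = np.asarray(r_distractor, dtype=float)
    stim = time_ms >= 0.0
    t = time_ms[stim]
    it = _first_sustained(rt[stim] >= theta, sustain_bins)
    idis = _first_sustained(rd[stim] >= theta, sustain_bins)
    if it is None and idis is None:
        return CHOICE_UNDECIDED, None
    if idis is None or (it is not None and it < idis):
        return CHOICE_TARGET, float(t[it])
    if it is None or idis < it:
        return CHOICE_DISTRACTOR, float(t[idis])
    # simultaneous crossing: higher rate wins, target on exact tie
    if rd[stim][idis] > rt[stim][it]:
        return CHOICE_DISTRACTOR, float(t[idis])
    return CHOICE_TARGET, float(t[it])


def _first_sustained(mask: np.ndarray, k: int) -> int | None:
    """Index at which ``mask`` has been True for k consecutive samples."""
    if k <= 1:
        idx = np.flatnonzero(mask)
        return int(idx[0]) if idx.size else None
    run = 0
    for i, v in enumerate(mask):
        run = run + 1 if v else 0
        if run >= k:
            return i
    return None


def baseline_difference(records_a: pd.DataFrame,
                        records_b: pd.DataFrame) -> float:
    """Difference of across-trial mean baseline rates (A minus B), Hz.

    With A = speed and B = neutral this is the paper-style Delta_ns; with
    A = neutral, B = accuracy it is Delta_na.
    """
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("baseline_difference requires non-empty record sets")
    return float(records_a.baseline_rate.mean() - records_b.baseline_rate.mean())


def trial_averaged_traces(result: SimulationResult, condition: str,
                          coherence: float) -> pd.DataFrame:
    """Mean target/distractor rate over correct trials, per time bin.

    Follows the figure convention of averaging correct trials only. Columns:
    t_ms, r_target_hz, r_distractor_hz, n_trials.
    """
    tr = result.traces[(condition, coherence)]
    recs = result.cell_records(condition, coherence)
    mask = (recs.correct == True).to_numpy()  # noqa: E712 (None-safe)
    if mask.sum() == 0:
        raise ValueError(
            f"no correct trials in cell ({condition}, {coherence})")
    return pd.DataFrame({
        "t_ms": tr.time_ms,
        "r_target_hz": tr.r_target[mask].mean(axis=0),
        "r_distractor_hz": tr.r_distractor[mask].mean(axis=0),
        "n_trials": int(mask.sum()),
    })
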