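"""Ideal-observer (signal-detection) analysis of simulated rate traces.

At each time bin the across-trial distribution of target-population rates is
compared with the distribution of distractor-population rates via the area
under the ROC curve (ties counted half). The discrimination time is the
first bin at which the AUC reaches a criterion and stays there for a sustain
window; the target rate at that moment, and its difference from the
condition's baseline rate (the discrimination-baseline difference),
approximate the "decision threshold" at which the populations separate --
distinct from, and lower than, the choice threshold.

An alternative per-trial reading defines the decision at the last
intersection of (smoothed) target and distractor traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .simulate import CellTraces, SimulationResult

__all__ = [
    "DiscriminationResult",
    "auc_timecourse",
    "discrimination_time",
    "rate_at_discrimination",
    "last_intersection_time",
    "discrimination_summary",
    "last_intersection_summary",
]

#: Default AUC criterion and sustain window (bins) for discrimination.
DEFAULT_CRITERION = 0.75
DEFAULT_SUSTAIN_BINS = 3
#: Default smoothing window for the last-intersection reading, ms.
DEFAULT_SMOOTH_MS = 50.0


@dataclass
class DiscriminationResult:
    """Time-resolved discriminability for one (condition, coherence) cell."""

    condition: str
    coherence: float
    time_ms: np.ndarray
    auc: np.ndarray
    criterion: float
    sustain_bins: int
    discrimination_time: float | None  # ms from stimulus onset
    rate_at_discrimination: float | None  # Hz, mean target rate at that time
    discrimination_baseline_diff: float | None  # Hz


def auc_timecourse(r_target: np.ndarray, r_distractor: np.ndarray) -> np.ndarray:
    """Per-bin ROC area comparing target-rate vs distractor-rate distributions.

    ``r_target`` (n1, n_bins) and ``r_distractor`` (n2, n_bins) hold rates
    across trials; the AUC at each bin is the probability that a random
    target sample exceeds a random distractor sample, ties counted half
    (the Mann-Whitney statistic).
    """
    rt = np.atleast_2d(np.asarray(r_target, dtype=float))
    rd = np.atleast_2d(np.asarray(r_distractor, dtype=float))
    n1, n2 = rt.shape[0], rd.shape[0]
    if n1 + n2 < 2 or n1 == 0 or n2 == 0 or rt.shape[1] == 0:
        raise ValueError("auc_timecourse needs non-empty samples per bin")
    if rt.shape[1] != rd.shape[1]:
        raise ValueError("target and distractor bins do not match")
    combined = np.vstack([rt, rd])
    ranks = rankdata(combined, method="average", axis=0)
    R1 = ranks[:n1].sum(axis=0)
    return (R1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)


def discrimination_time(time_ms: np.ndarray, auc: np.ndarray,
                        criterion: float = DEFAULT_CRITERION,
                        sustain_bins: int = DEFAULT_SUSTAIN_BINS,
                        ) -> float | None:
    """First time the AUC reaches ``criterion`` for ``sustain_bins`` bins.

    Returns None (an explicit absent value) if the criterion is never
    sustained.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    mask = np.asarray(auc, dtype=float) >= criterion
    if sustain_bins <= 1:
        idx = np.flatnonzero(mask)
        return float(time_ms[idx[0]]) if idx.size else None
    width = mask.size - sustain_bins + 1
    if width <= 0:
        return None
    run = mask[:width].copy()
    for s in range(1, sustain_bins):
        run &= mask[s:s + width]
    idx = np.flatnonzero(run)
    return float(time_ms[idx[0]]) if idx.size else None


def rate_at_discrimination(traces: CellTraces, t_disc: float,
                           baseline_rate: float) -> tuple[float, float]:
    """Mean target rate at the discrimination time and its baseline difference.

    Returns ``(rate, rate - baseline_rate)`` in Hz.
    """
    if t_disc is None:
        raise ValueError("discrimination time is absent")
    idx = int(np.argmin(np.abs(traces.time_ms - t_disc)))
    rate = float(traces.r_target[:, idx].mean())
    return rate, rate - baseline_rate


def _smooth(trace: np.ndarray, window_bins: int) -> np.ndarray:
    """Centered moving average with edge truncation."""
    if window_bins <= 1:
        return np.asarray(trace, dtype=float)
    kernel = np.ones(window_bins) / window_bins
    padded = np.pad(np.asarray(trace, dtype=float),
                    (window_bins // 2, window_bins - 1 - window_bins // 2),
                    mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def last_intersection_time(time_ms: np.ndarray, r_target: np.ndarray,
                           r_distractor: np.ndarray,
                           smooth_ms: float = DEFAULT_SMOOTH_MS,
                           ) -> tuple[float | None, str]:
    """Last crossing of smoothed target/distractor traces during the stimulus.

    Returns ``(t_cross, implied_choice)`` where the implied choice is the
    population with the higher smoothed rate after the last crossing. If the
    traces never cross during the stimulus epoch, the crossing time is None
    and the implied choice is the initially higher population.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    stim = time_ms >= 0.0
    t = time_ms[stim]
    if t.size < 2:
        raise ValueError("need at least two stimulus-epoch samples")
    dt_bin = t[1] - t[0]
    wb = max(1, int(round(smooth_ms / dt_bin)))
    diff = (_smooth(np.asarray(r_target, float)[stim], wb)
            - _smooth(np.asarray(r_distractor, float)[stim], wb))
    sign = np.sign(diff)
    nzpos = np.flatnonzero(sign != 0)
    if nzpos.size == 0:
        return None, "target"
    flips = np.flatnonzero(sign[nzpos[:-1]] != sign[nzpos[1:]])
    if flips.size == 0:
        return None, "target" if sign[nzpos[0]] > 0 else "distractor"
    i0, i1 = int(nzpos[flips[-1]]), int(nzpos[flips[-1] + 1])
    if i1 == i0 + 1:
        # linear interpolation of the zero crossing between the two samples
        frac = diff[i0] / (diff[i0] - diff[i1])
        t_cross = float(t[i0] + frac * dt_bin)
    else:
        # the traces touch exactly at intervening sample(s)
        t_cross = float(t[i1 - 1])
    choice = "target" if sign[i1] > 0 else "distractor"
    return t_cross, choice


def discrimination_summary(result: SimulationResult,
                           criterion: float = DEFAULT_CRITERION,
                           sustain_bins: int = DEFAULT_SUSTAIN_BINS,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell and pooled ideal-observer discrimination summaries.

    Returns ``(per_cell, pooled)``. The pooled table implements the
    across-positive-coherence variant: for each condition, the unweighted
    mean over positive coherences of the target rate at each coherence's own
    discrimination time, and that mean minus the condition's mean baseline
    rate.
    """
    cell_rows = []
    for (cond, c), traces in sorted(result.traces.items()):
        auc = auc_timecourse(traces.r_target[:, traces.stim_mask],
                             traces.r_distractor[:, traces.stim_mask])
        t_stim = traces.time_ms[traces.stim_mask]
        t_disc = discrimination_time(t_stim, auc, criterion, sustain_bins)
        baseline = result.mean_baseline_rate(cond)
        if t_disc is None:
            rate = diff = None
        else:
            rate, diff = rate_at_discrimination(traces, t_disc, baseline)
        cell_rows.append({"condition": cond, "coherence": c,
                          "discrimination_time": t_disc,
                          "rate_at_discrimination": rate,
                          "discrimination_baseline_diff": diff,
                          "baseline_rate": baseline})
    per_cell = pd.DataFrame(cell_rows)
    pooled_rows = []
    for cond, grp in per_cell.groupby("condition", sort=True):
        pos = grp[(grp.coherence > 0)
                  & grp.rate_at_discrimination.notna()]
        if pos.empty:
            pooled_rows.append({"condition": cond, "n_coherences": 0,
                                "rate_at_discrimination": np.nan,
                                "discrimination_baseline_diff": np.nan,
                                "mean_discrimination_time": np.nan})
            continue
        rate = float(pos.rate_at_discrimination.mean())
        baseline = float(grp.baseline_rate.iloc[0])
        pooled_rows.append({
            "condition": cond, "n_coherences": len(pos),
            "rate_at_discrimination": rate,
            "discrimination_baseline_diff": rate - baseline,
            "mean_discrimination_time":
                float(pos.discrimination_time.mean()),
        })
    return per_cell, pd.DataFrame(pooled_rows)


def last_intersection_summary(result: SimulationResult,
                              smooth_ms: float = DEFAULT_SMOOTH_MS,
                              ) -> pd.DataFrame:
    """Per-condition summary of the last-intersection reading.

    For every trial of every positive-coherence cell: the last crossing time
    of smoothed traces, the target rate there, and the implied choice. The
    summary reports the mean rate at separation, its baseline difference,
    and the concordance of the implied choice with the threshold-crossing
    choice on trials where both are decided.
    """
    rows = []
    for (cond, c), traces in sorted(result.traces.items()):
        if c <= 0:
            continue
        recs = result.cell_records(cond, c)
        choices = recs.choice.to_numpy()
        t_stim_mask = traces.stim_mask
        t = traces.time_ms
        for j in range(traces.r_target.shape[0]):
            t_cross, implied = last_intersection_time(
                t, traces.r_target[j], traces.r_distractor[j], smooth_ms)
            if t_cross is None:
                rate = np.nan
            else:
                idx = int(np.argmin(np.abs(t - t_cross)))
                rate = float(traces.r_target[j, idx])
            rows.append({"condition": cond, "coherence": c, "trial": j,
                         "t_cross": t_cross, "rate_at_cross": rate,
                         "implied_choice": implied,
                         "threshold_choice": choices[j]})
    per_trial = pd.DataFrame(rows)
    out = []
    for cond, grp in per_trial.groupby("condition", sort=True):
        crossed = grp[grp.t_cross.notna()]
        decided = grp[grp.threshold_choice != "undecided"]
        agree = (decided.implied_choice == decided.threshold_choice).mean() \
            if len(decided) else np.nan
        baseline = result.mean_baseline_rate(cond)
        rate = float(crossed.rate_at_cross.mean()) if len(crossed) else np.nan
        out.append({"condition": cond,
                    "mean_rate_at_separation": rate,
                    "separation_baseline_diff": rate - baseline,
                    "concordance": float(agree),
                    "n_crossed": len(crossed), "n_trials": len(grp)})
    return pd.DataFrame(out)
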