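"""Psychometric/chronometric summaries and the threshold-compensation
experiment.

The psychometric curve is fit per condition with a Weibull function

    P(c) = 0.5 + 0.5 * (1 - exp(-(c / alpha)**beta))

by binomial maximum likelihood; the coherence at 75% accuracy follows in
closed form, c75 = alpha * ln(2)**(1/beta).

The compensation experiment asks whether reinstating the neutral condition's
threshold-baseline difference -- raising the speed threshold by Delta_ns and
lowering the accuracy threshold by Delta_na -- recovers neutral behavior.
Choices are re-detected from stored rate traces for every threshold in a
grid (a paired design: the same trials under every threshold), so adjusted
and unadjusted results differ only through the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .simulate import CellTraces, SimulationResult

__all__ = [
    "PsychometricFit",
    "PsychometricFitError",
    "fit_psychometric",
    "accuracy_table",
    "chronometric_summary",
    "threshold_sweep",
    "compensation_summary",
    "redetect_cell",
]

logger = logging.getLogger(__name__)

#: Default threshold grid for the compensation sweep, Hz.
DEFAULT_THETA_GRID: tuple[float, ...] = tuple(float(t) for t in range(9, 22))

#: Fraction of trials crossing theta before stimulus onset above which a
#: sweep cell is flagged as broken down (threshold inside baseline noise).
BREAKDOWN_FRACTION = 0.05


class PsychometricFitError(RuntimeError):
    """Raised when the Weibull fit cannot be estimated from the data."""


@dataclass
class PsychometricFit:
    """Weibull psychometric fit with per-coherence observations."""

    alpha: float  # scale, percent coherence
    beta: float  # shape, dimensionless
    coherences: np.ndarray
    n_correct: np.ndarray
    n_total: np.ndarray
    log_likelihood: float

    @property
    def c75(self) -> float:
        """Coherence at 75% accuracy: alpha * ln(2)**(1/beta)."""
        return self.alpha * np.log(2.0) ** (1.0 / self.beta)

    def predict(self, c):
        """Predicted probability correct at coherence(s) ``c`` (percent)."""
        c = np.asarray(c, dtype=float)
        with np.errstate(divide="ignore"):
            p = 0.5 + 0.5 * (1.0 - np.exp(-(c / self.alpha) ** self.beta))
        return p if p.ndim else float(p)


def fit_psychometric(coherences, n_correct, n_total) -> PsychometricFit:
    """Binomial maximum-likelihood Weibull fit of accuracy vs coherence.

    ``coherences`` in percent; requires at least three levels with trials.
    The c = 0 level contributes its ~50% cell (the curve passes through 0.5
    there by construction).
    """
    c = np.asarray(coherences, dtype=float)
    k = np.asarray(n_correct, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if c.size < 3 or np.any(n < 1):
        raise PsychometricFitError(
            "need >= 3 coherence levels with >= 1 trial each")
    if np.any(k > n) or np.any(k < 0):
        raise PsychometricFitError("n_correct must lie in [0, n_total]")
    obs = k / n
    pos = c > 0
    if not pos.any() or np.ptp(obs[pos]) < 1e-12 and np.all(obs[pos] < 0.55):
        raise PsychometricFitError(
            f"degenerate accuracy data (no coherence dependence): {obs}")

    def nll(log_params):
        alpha, beta = np.exp(log_params)
        with np.errstate(divide="ignore", over="ignore"):
            p = 0.5 + 0.5 * (1.0 - np.exp(-(c / alpha) ** beta))
        p = np.clip(p, 0.5, 1.0 - 1e-12)
        # c=0 gives p=0.5 exactly; clip only guards the upper tail
        ll = k * np.log(p) + (n - k) * np.log1p(-p)
        return -float(np.sum(ll))

    # initial alpha: coherence where observed accuracy first exceeds 75%
    above = c[pos][obs[pos] >= 0.75]
    alpha0 = float(above.min()) if above.size else float(np.max(c[pos]))
    best = None
    for beta0 in (1.0, 1.5, 3.0):
        res = minimize(nll, np.log([max(alpha0, 1e-3), beta0]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10,
                                "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = np.exp(best.x)
    if not best.success or not np.isfinite(alpha) or not np.isfinite(beta) \
            or alpha <= 0 or beta <= 0 or alpha > 1e4:
        raise PsychometricFitError(
            f"Weibull fit failed: {best.message}; obs={obs}")
    return PsychometricFit(float(alpha), float(beta), c, k.astype(int),
                           n.astype(int), -best.fun)


def accuracy_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per (condition, coherence): n_correct, n_decided, n_undecided, accuracy.

    Undecided trials are excluded from accuracy (reported separately).
    """
    rows = []
    for (cond, c), grp in records.groupby(["condition", "coherence"],
                                          sort=True):
        decided = grp[grp.choice != "undecided"]
        n_corr = int((decided.correct == True).sum())  # noqa: E712
        rows.append({
            "condition": cond, "coherence": c, "n_correct": n_corr,
            "n_decided": len(decided),
            "n_undecided": len(grp) - len(decided),
            "accuracy": n_corr / len(decided) if len(decided) else np.nan,
        })
    return pd.DataFrame(rows)


def fit_condition_psychometric(records: pd.DataFrame,
                               condition: str) -> PsychometricFit:
    """Weibull fit for one condition from trial records."""
    tab = accuracy_table(records[records.condition == condition])
    tab = tab[tab.n_decided > 0]
    return fit_psychometric(tab.coherence.to_numpy(),
                            tab.n_correct.to_numpy(),
                            tab.n_decided.to_numpy())


def chronometric_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean decision time +/- SE per (condition, coherence, correct).

    Undecided trials are excluded. SE is NaN (flagged) for single-trial
    cells. An additional pooled row (correct = 'all') covers all decided
    trials per cell.
    """
    if records.empty:
        raise ValueError("chronometric_summary requires non-empty records")
    decided = records[records.choice != "undecided"].copy()
    rows = []
    for (cond, c), grp in decided.groupby(["condition", "coherence"],
                                          sort=True):
        subsets = {"correct": grp[grp.correct == True],  # noqa: E712
                   "error": grp[grp.correct == False],  # noqa: E712
                   "all": grp}
        for label, sub in subsets.items():
            dt = sub.decision_time.to_numpy(dtype=float)
            if dt.size == 0:
                continue
            se = dt.std(ddof=1) / np.sqrt(dt.size) if dt.size > 1 else np.nan
            rows.append({"condition": cond, "coherence": c, "trials": label,
                         "mean_dt": float(dt.mean()), "se_dt": se,
                         "n": int(dt.size)})
    return pd.DataFrame(rows)


def redetect_cell(traces: CellTraces, theta: float,
                  sustain_bins: int = 1) -> pd.DataFrame:
    """Re-detect choices for every trial of a cell at threshold ``theta``.

    Vectorized first-crossing detection on the stored rate traces (stimulus
    epoch only). Returns columns: choice, decision_time, correct,
    prestim_crossing (whether either rate exceeded theta before onset).
    """
    stim = traces.stim_mask
    t = traces.time_ms[stim]
    rt = traces.r_target[:, stim]
    rd = traces.r_distractor[:, stim]

    def first_idx(mask2d):
        if sustain_bins > 1:
            width = mask2d.shape[1] - sustain_bins + 1
            run = mask2d[:, :width].copy()
            for s in range(1, sustain_bins):
                run &= mask2d[:, s:s + width]
            m = np.zeros_like(mask2d)
            m[:, sustain_bins - 1:] = run
            mask2d = m
        any_hit = mask2d.any(axis=1)
        idx = mask2d.argmax(axis=1)
        return np.where(any_hit, idx, mask2d.shape[1])

    it = first_idx(rt >= theta)
    idis = first_idx(rd >= theta)
    n_bins = rt.shape[1]
    decided = (it < n_bins) | (idis < n_bins)
    target_wins = it < idis
    tie = decided & (it == idis)
    if tie.any():
        rows = np.flatnonzero(tie)
        target_wins[rows] = rt[rows, it[rows]] >= rd[rows, it[rows]]
    choice = np.where(~decided, "undecided",
                      np.where(target_wins, "target", "distractor"))
    first = np.minimum(it, idis)
    dtimes = np.where(decided, t[np.clip(first, 0, n_bins - 1)], np.nan)
    prestim = ((traces.r_target[:, ~stim] >= theta)
               | (traces.r_distractor[:, ~stim] >= theta)).any(axis=1)
    return pd.DataFrame({
        "choice": choice,
        "decision_time": dtimes,
        "correct": np.where(~decided, None, target_wins.astype(object)),
        "prestim_crossing": prestim,
    })


def _sweep_entry(result: SimulationResult, condition: str, theta_eff: float,
                 sustain_bins: int, probe_coherences) -> dict:
    """c75 and probe decision times for one condition at one threshold."""
    cohs, n_corr, n_dec = [], [], []
    probe_dt: dict[float, tuple[float, float, int]] = {}
    breakdown = False
    for (cond, c), traces in sorted(result.traces.items()):
        if cond != condition:
            continue
        det = redetect_cell(traces, theta_eff, sustain_bins)
        decided = det[det.choice != "undecided"]
        cohs.append(c)
        n_corr.append(int((decided.correct == True).sum()))  # noqa: E712
        n_dec.append(len(decided))
        if det.prestim_crossing.mean() > BREAKDOWN_FRACTION:
            breakdown = True
        if c in probe_coherences:
            dt = decided.decision_time.to_numpy(dtype=float)
            if dt.size:
                se = dt.std(ddof=1) / np.sqrt(dt.size) if dt.size > 1 \
                    else np.nan
                probe_dt[c] = (float(dt.mean()), float(se), int(dt.size))
            else:
                probe_dt[c] = (np.nan, np.nan, 0)
    entry: dict = {"breakdown": breakdown, "fit_ok": True}
    degenerate = all(nd == 0 for nd in n_dec)
    if degenerate:
        entry.update(c75=np.nan, alpha=np.nan, beta=np.nan, fit_ok=False)
    else:
        try:
            keep = [i for i, nd in enumerate(n_dec) if nd > 0]
            fit = fit_psychometric(np.array(cohs)[keep],
                                   np.array(n_corr)[keep],
                                   np.array(n_dec)[keep])
            entry.update(c75=fit.c75, alpha=fit.alpha, beta=fit.beta)
        except PsychometricFitError as err:
            logger.warning("psychometric fit failed (%s, theta=%.3g): %s",
                           condition, theta_eff, err)
            entry.update(c75=np.nan, alpha=np.nan, beta=np.nan, fit_ok=False)
    for c, (m, se, n) in probe_dt.items():
        entry[f"dt_c{c:g}"] = m
        entry[f"dt_c{c:g}_se"] = se
        entry[f"dt_c{c:g}_n"] = n
    return entry


def threshold_sweep(result: SimulationResult,
                    theta_grid=DEFAULT_THETA_GRID,
                    delta_ns: float | None = None,
                    delta_na: float | None = None,
                    probe_coherences=(1.0, 32.0),
                    sustain_bins: int = 1) -> pd.DataFrame:
    """Paired threshold-compensation sweep from stored traces.

    For each threshold in the grid and each condition: the unadjusted
    result; additionally, for speed the result at ``theta + delta_ns`` and
    for accuracy at ``theta - delta_na`` (the neutral condition is never
    adjusted). Deltas default to the baseline differences measured from the
    result's own records. Decision times at the probe coherences pool
    correct and error trials.
    """
    from .simulate import baseline_difference

    recs = result.records
    if delta_ns is None:
        delta_ns = baseline_difference(recs[recs.condition == "speed"],
                                       recs[recs.condition == "neutral"])
    if delta_na is None:
        delta_na = baseline_difference(recs[recs.condition == "neutral"],
                                       recs[recs.condition == "accuracy"])
    probe_coherences = tuple(float(c) for c in probe_coherences)
    conditions = sorted({k[0] for k in result.traces})
    rows = []
    for theta in theta_grid:
        for cond in conditions:
            variants = [(False, float(theta))]
            if cond == "speed":
                variants.append((True, float(theta) + delta_ns))
            elif cond == "accuracy":
                variants.append((True, float(theta) - delta_na))
            for adjusted, theta_eff in variants:
                entry = _sweep_entry(result, cond, theta_eff, sustain_bins,
                                     probe_coherences)
                entry.update(condition=cond, theta=float(theta),
                             adjusted=adjusted, theta_eff=theta_eff,
                             delta_ns=delta_ns, delta_na=delta_na)
                rows.append(entry)
    cols = ["condition", "theta", "adjusted", "theta_eff", "c75", "alpha",
            "beta", "fit_ok", "breakdown", "delta_ns", "delta_na"]
    df = pd.DataFrame(rows)
    return df[cols + [c for c in df.columns if c not in cols]]


def compensation_summary(sweep: pd.DataFrame,
                         measures=("c75", "dt_c1", "dt_c32")) -> pd.DataFrame:
    """Fraction of the condition-neutral gap closed by threshold adjustment.

    For each threshold, condition (speed/accuracy) and measure:
    ``closed = (adjusted - unadjusted) / (neutral - unadjusted)``, so 0
    means the adjustment did nothing and 1 means it fully recovered neutral
    behavior. Also reports whether the adjusted value remains separated from
    neutral by more than twice the combined Monte-Carlo SE (decision-time
    measures only; NaN where no SE is defined).
    """
    rows = []
    for theta in sorted(sweep.theta.unique()):
        at = sweep[sweep.theta == theta]
        neutral = at[(at.condition == "neutral") & (~at.adjusted)].iloc[0]
        for cond in ("speed", "accuracy"):
            unadj = at[(at.condition == cond) & (~at.adjusted)].iloc[0]
            adj = at[(at.condition == cond) & (at.adjusted)].iloc[0]
            for m in measures:
                gap = neutral[m] - unadj[m]
                closed = (adj[m] - unadj[m]) / gap if gap != 0 else np.nan
                se_col = f"{m}_se"
                if se_col in at.columns and np.isfinite(adj.get(se_col, np.nan)):
                    comb = np.sqrt(adj[se_col] ** 2 + neutral[se_col] ** 2)
                    separated = bool(abs(adj[m] - neutral[m]) > 2.0 * comb)
                else:
                    separated = None
                rows.append({"theta": theta, "condition": cond, "measure": m,
                             "neutral": neutral[m], "unadjusted": unadj[m],
                             "adjusted": adj[m], "fraction_closed": closed,
                             "separated_from_neutral": separated})
    return pd.DataFrame(rows)
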