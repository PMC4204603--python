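"""Weibull psychometrics, chronometric summaries and the threshold sweep."""

import numpy as np
import pandas as pd
import pytest

from satnet import chronometric_summary, fit_psychometric, threshold_sweep
from satnet.behavior import (PsychometricFitError, accuracy_table,
                             compensation_summary, redetect_cell)
from satnet.simulate import detect_choice


class TestPsychometricFit:
    COHS = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0])

    @staticmethod
    def weibull(c, alpha, beta):
        return 0.5 + 0.5 * (1 - np.exp(-(c / alpha) ** beta))

    def test_curve_value_at_alpha(self):
        rng = np.random.default_rng(0)
        p = self.weibull(self.COHS, 6.0, 1.5)
        n = 20000
        k = rng.binomial(n, p)
        fit = fit_psychometric(self.COHS, k, np.full_like(k, n))
        assert fit.predict(fit.alpha) == pytest.approx(
            0.5 + 0.5 * (1 - np.exp(-1.0)), abs=1e-12)

    def test_c75_closed_form(self):
        rng = np.random.default_rng(1)
        p = self.weibull(self.COHS, 6.0, 1.5)
        k = rng.binomial(5000, p)
        fit = fit_psychometric(self.COHS, k, np.full_like(k, 5000))
        assert fit.c75 == pytest.approx(
            fit.alpha * np.log(2.0) ** (1 / fit.beta), abs=1e-12)
        # generating parameters give c75 = 6 * ln2^(1/1.5) ~ 4.6993
        assert 6.0 * np.log(2.0) ** (1 / 1.5) == pytest.approx(4.69932,
                                                               abs=5e-5)

    def test_parameter_recovery_moderate_n(self):
        rng = np.random.default_rng(2)
        alpha, beta, n = 6.0, 1.5, 100_000
        k = rng.binomial(n, self.weibull(self.COHS, alpha, beta))
        fit = fit_psychometric(self.COHS, k, np.full_like(k, n))
        assert fit.alpha == pytest.approx(alpha, rel=0.03)
        assert fit.beta == pytest.approx(beta, rel=0.06)

    def test_degenerate_data_rejected(self):
        with pytest.raises(PsychometricFitError):
            fit_psychometric([0, 4, 8], [50, 50, 50], [100, 100, 100])
        with pytest.raises(PsychometricFitError):
            fit_psychometric([0, 4], [50, 80], [100, 100])


class TestChronometricSummary:
    def _records(self, dts, corrects):
        return pd.DataFrame({
            "condition": "neutral", "coherence": 4.0,
            "choice": ["target"] * len(dts),
            "decision_time": dts, "correct": corrects,
            "baseline_rate": 2.0})

    def test_two_trial_mean_and_se(self):
        out = chronometric_summary(self._records([400.0, 600.0],
                                                 [True, True]))
        row = out[out.trials == "correct"].iloc[0]
        assert row.mean_dt == 500.0
        assert row.se_dt == pytest.approx(100.0)
        assert row.n == 2

    def test_single_trial_se_flagged(self):
        out = chronometric_summary(self._records([500.0], [True]))
        row = out[out.trials == "correct"].iloc[0]
        assert row.mean_dt == 500.0 and np.isnan(row.se_dt)

    def test_undecided_trials_excluded(self, small_result):
        out = chronometric_summary(small_result.records)
        assert (out.n > 0).all()
        assert out.mean_dt.notna().all()


class TestRedetection:
    def test_matches_scalar_detector(self, small_result):
        tr = small_result.traces[("neutral", 8.0)]
        det = redetect_cell(tr, theta=15.0)
        for j in range(tr.r_target.shape[0]):
            choice, dt = detect_choice(tr.time_ms, tr.r_target[j],
                                       tr.r_distractor[j], 15.0)
            assert det.choice.iloc[j] == choice
            if dt is None:
                assert np.isnan(det.decision_time.iloc[j])
            else:
                assert det.decision_time.iloc[j] == dt

    def test_raising_threshold_weakly_slows_and_never_undoes(self,
                                                             small_result):
        tr = small_result.traces[("speed", 8.0)]
        low = redetect_cell(tr, theta=12.0)
        high = redetect_cell(tr, theta=18.0)
        for j in range(len(low)):
            if high.choice.iloc[j] != "undecided":
                assert low.choice.iloc[j] != "undecided"
                assert (high.decision_time.iloc[j]
                        >= low.decision_time.iloc[j])


class TestThresholdSweep:
    def test_zero_adjustment_is_identity(self, small_result):
        sweep = threshold_sweep(small_result, [15.0], delta_ns=0.0,
                                delta_na=0.0, probe_coherences=(8.0, 32.0))
        for cond in ("speed", "accuracy"):
            adj = sweep[(sweep.condition == cond) & sweep.adjusted]
            unadj = sweep[(sweep.condition == cond) & ~sweep.adjusted]
            for col in ("c75", "dt_c8", "dt_c32", "theta_eff"):
                a, u = adj[col].iloc[0], unadj[col].iloc[0]
                assert (a == u) or (np.isnan(a) and np.isnan(u))

    def test_neutral_never_adjusted(self, small_result):
        sweep = threshold_sweep(small_result, [14.0, 15.0],
                                probe_coherences=(8.0, 32.0))
        neutral = sweep[sweep.condition == "neutral"]
        assert not neutral.adjusted.any()
        speed_adj = sweep[(sweep.condition == "speed") & sweep.adjusted]
        assert np.allclose(speed_adj.theta_eff,
                           speed_adj.theta + speed_adj.delta_ns)

    def test_compensation_summary_identity_case(self, small_result):
        sweep = threshold_sweep(small_result, [15.0], delta_ns=0.0,
                                delta_na=0.0, probe_coherences=(8.0, 32.0))
        comp = compensation_summary(sweep, ("dt_c8", "dt_c32"))
        # zero adjustment closes exactly none of the gap
        assert np.allclose(comp.fraction_closed.astype(float), 0.0)


class TestAccuracyTable:
    def test_counts_and_undecided_bookkeeping(self, small_result):
        tab = accuracy_table(small_result.records)
        n = small_result.records.groupby(
            ["condition", "coherence"]).size().iloc[0]
        assert ((tab.n_decided + tab.n_undecided) == n).all()
        assert ((tab.n_correct <= tab.n_decided)).all()
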