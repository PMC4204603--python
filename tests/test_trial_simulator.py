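"""Trial integration, choice detection and baseline statistics."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from satnet import (ConditionSpec, ModelParameters, baseline_difference,
                    detect_choice, run_batch, run_trial,
                    trial_averaged_traces)
from satnet.params import EpochSchedule


@pytest.fixture(scope="module")
def noiseless_neutral():
    return ConditionSpec("neutral", 0.321, sigma_noise=0.0)


class TestDetectChoice:
    def test_target_first_crossing(self):
        t = np.arange(-100.0, 1000.0, 10.0)
        rt = np.where(t >= 800.0, 20.0, 5.0)
        rd = np.full_like(t, 5.0)
        choice, dt = detect_choice(t, rt, rd, theta=15.0)
        assert (choice, dt) == ("target", 800.0)

    def test_no_crossing_is_undecided(self):
        t = np.arange(0.0, 1000.0, 10.0)
        low = np.full_like(t, 5.0)
        assert detect_choice(t, low, low, theta=15.0) == ("undecided", None)

    def test_first_crossing_rule_prefers_earlier_population(self):
        t = np.arange(0.0, 1000.0, 10.0)
        rt = np.where(t >= 900.0, 20.0, 5.0)
        rd = np.where(t >= 600.0, 20.0, 5.0)
        choice, dt = detect_choice(t, rt, rd, theta=15.0)
        assert (choice, dt) == ("distractor", 600.0)

    def test_prestimulus_samples_ignored(self):
        t = np.arange(-500.0, 500.0, 10.0)
        rt = np.where(t < 0.0, 20.0, 5.0)  # crossing only before onset
        rd = np.full_like(t, 5.0)
        assert detect_choice(t, rt, rd, theta=15.0) == ("undecided", None)

    def test_sustained_crossing_requirement_skips_single_blip(self):
        t = np.arange(0.0, 500.0, 10.0)
        rt = np.full_like(t, 5.0)
        rt[10] = 20.0  # one-bin excursion
        rt[30:] = 20.0
        rd = np.full_like(t, 5.0)
        choice, dt = detect_choice(t, rt, rd, theta=15.0, sustain_bins=3)
        assert choice == "target"
        assert dt == t[32]


class TestNoiselessDynamics:
    def test_deterministic_repeatable_choice(self, noiseless_neutral):
        sched = EpochSchedule(dt=0.5)
        recs = []
        for trial in (0, 1, 7):
            rec, _ = run_trial(noiseless_neutral, 8.0, sched,
                               trial_index=trial)
            recs.append(rec)
        assert all(r.choice == "target" for r in recs)
        assert len({r.decision_time for r in recs}) == 1
        assert all(r.correct for r in recs)

    def test_zero_coherence_preserves_symmetry(self, noiseless_neutral):
        # on the S1 = S2 diagonal nothing can break the tie; the symmetric
        # trajectory approaches the saddle (~5 Hz), far below theta = 15 Hz
        sched = EpochSchedule(dt=0.5)
        rec, traces = run_trial(noiseless_neutral, 0.0, sched)
        assert rec.choice == "undecided"
        assert rec.decision_time is None and rec.correct is None
        assert np.allclose(traces.r_target, traces.r_distractor)


class TestBatch:
    def test_single_trial_per_cell_counts(self, conditions, fast_sched):
        res = run_batch(conditions[:2], [0.0, 8.0], 1, fast_sched,
                        master_seed=3)
        assert len(res.records) == 4
        assert set(res.traces) == {("speed", 0.0), ("speed", 8.0),
                                   ("neutral", 0.0), ("neutral", 8.0)}

    def test_reproducible_under_master_seed(self, conditions, fast_sched):
        a = run_batch(conditions[:1], [8.0], 5, fast_sched, master_seed=11)
        b = run_batch(conditions[:1], [8.0], 5, fast_sched, master_seed=11)
        pdt.assert_frame_equal(a.records, b.records)
        ta, tb = a.traces[("speed", 8.0)], b.traces[("speed", 8.0)]
        assert np.array_equal(ta.r_target, tb.r_target)
        assert np.array_equal(ta.r_distractor, tb.r_distractor)

    def test_single_trial_matches_batch_slot(self, conditions, fast_sched):
        batch = run_batch(conditions[:1], [8.0], 6, fast_sched,
                          master_seed=21)
        rec, traces = run_trial(conditions[0], 8.0, fast_sched,
                                master_seed=21, cond_index=0, coh_index=0,
                                trial_index=3)
        row = batch.records.iloc[3]
        assert rec.choice == row.choice
        assert rec.decision_time == row.decision_time
        assert rec.baseline_rate == row.baseline_rate
        assert np.array_equal(traces.r_target[0],
                              batch.traces[("speed", 8.0)].r_target[3])

    def test_rates_nonnegative_and_time_grid_increasing(self, small_result):
        for tr in small_result.traces.values():
            assert np.all(np.diff(tr.time_ms) > 0)
            assert np.all(tr.r_target >= 0) and np.all(tr.r_distractor >= 0)

    def test_decision_times_within_stimulus_epoch(self, small_result):
        decided = small_result.records.dropna(subset=["decision_time"])
        assert (decided.decision_time > 0).all()
        assert (decided.decision_time
                <= small_result.schedule.t_stim).all()


class TestBaselines:
    def test_identical_sets_give_zero_difference(self, small_result):
        recs = small_result.records
        a = recs[recs.condition == "speed"]
        assert baseline_difference(a, a) == 0.0

    def test_background_current_orders_baselines(self, small_result):
        recs = small_result.records
        d_ns = baseline_difference(recs[recs.condition == "speed"],
                                   recs[recs.condition == "neutral"])
        d_na = baseline_difference(recs[recs.condition == "neutral"],
                                   recs[recs.condition == "accuracy"])
        assert d_ns > 0 and d_na > 0

    def test_empty_input_rejected(self, small_result):
        recs = small_result.records
        with pytest.raises(ValueError):
            baseline_difference(recs.iloc[:0], recs)


class TestAveragedTraces:
    def test_correct_trial_average_shape(self, small_result):
        df = trial_averaged_traces(small_result, "neutral", 8.0)
        tr = small_result.traces[("neutral", 8.0)]
        assert len(df) == len(tr.time_ms)
        n_correct = int((small_result.cell_records("neutral", 8.0)
                         .correct == True).sum())  # noqa: E712
        assert (df.n_trials == n_correct).all()
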