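"""The closed-loop controller: baseline, bar dynamics, sham replay, and
the double-blind condition schedule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import betanf as b
from betanf.engine import (
    REPLAY_BASELINE_VALUES,
    ReplayBuffer,
    sham_decoupling_r,
)
from betanf.spectral import BetaTimeseries

FS = 500.0


def _stream(values, t0=0.0):
    values = np.asarray(values, dtype=float)
    return BetaTimeseries(
        times_s=t0 + 0.25 * np.arange(1, len(values) + 1),
        values=values, band_hz=(16, 26),
    )


class TestTrialBaseline:
    def test_constant_stream(self):
        s = _stream([3.0] * 20)
        assert b.trial_baseline(s, 5.0) == pytest.approx(3.0)

    def test_mean_of_eight_grid_values(self):
        # values 1..8 timestamped within the 2 s before pre-cue onset at 2.0 s
        s = _stream(np.arange(1, 9), t0=0.0)
        assert b.trial_baseline(s, 2.0) == pytest.approx(4.5)

    def test_insufficient_history_raises(self):
        s = _stream([1.0, 2.0], t0=10.0)
        with pytest.raises(ValueError):
            b.trial_baseline(s, 5.0)

    def test_artifact_window_shifts_raw_baseline(self):
        """Cleaning the stream before baselining changes the result when an
        artifact window sits in the baseline."""
        from betanf.spectral import clean_outliers

        values = np.full(12, 2.0) + np.arange(12) * 1e-3
        values[5] = 500.0
        s = _stream(values)
        raw = b.trial_baseline(s, 3.0)
        cleaned = b.trial_baseline(clean_outliers(s), 3.0)
        assert raw != pytest.approx(cleaned)
        assert cleaned == pytest.approx(2.0, abs=0.05)


class TestUpdateBar:
    def test_left_step_below_desync_threshold(self):
        state = b.update_bar(b.BarState(), -10.0, -5.0, 5.0)
        assert state.position_px == -20
        assert state.step_log[-1]["decision"] == "left"

    def test_right_step_above_sync_threshold(self):
        state = b.update_bar(b.BarState(), 10.0, -5.0, 5.0)
        assert state.position_px == 20

    def test_recenter_from_minus_40(self):
        state = b.BarState(position_px=-40)
        b.update_bar(state, 0.0, -5.0, 5.0)
        assert state.position_px == -30

    def test_recenter_never_crosses_zero(self):
        state = b.BarState(position_px=-5)
        b.update_bar(state, 0.0, -5.0, 5.0)
        assert state.position_px == 0

    def test_edge_clamp(self):
        state = b.BarState(position_px=-400)
        b.update_bar(state, -10.0, -5.0, 5.0)
        assert state.position_px == -400

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            b.update_bar(b.BarState(), 0.0, 5.0, -5.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-20, max_value=20), min_size=1,
                    max_size=60))
    def test_step_sizes_and_log_reconstruction(self, d_betas):
        """|step| is always 0, 10 or 20 px; the final position is exactly
        reproducible from the step log."""
        state = b.BarState()
        prev = 0
        for d in d_betas:
            b.update_bar(state, d, -5.0, 5.0)
            step = state.position_px - prev
            assert abs(step) in (0, 10, 20)
            if state.step_log[-1]["decision"] == "recenter":
                assert abs(state.position_px) <= abs(prev)
                assert np.sign(state.position_px) in (0, np.sign(prev))
            prev = state.position_px
        assert state.step_log[-1]["position_px"] == state.position_px


class TestReplayBuffer:
    def test_sequential_then_wrap_with_notice(self):
        buf = ReplayBuffer(np.arange(5, dtype=float))
        assert np.array_equal(buf.draw(3), [0, 1, 2])
        with pytest.warns(UserWarning, match="wrap"):
            out = buf.draw(4)
        assert np.array_equal(out, [3, 4, 0, 1])
        assert buf.n_wraps == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ReplayBuffer(np.array([]))


@pytest.fixture(scope="module")
def nf_setup(default_calibration, default_calibration_session):
    prof, _, cal_rec, _ = default_calibration_session
    agent = b.AgentModel(profile=prof, desync_gain=0.6, sync_gain=0.0)
    sched = b.build_nf_schedule(seed=17)
    rec, markers = b.synthesize_session(prof, sched, agent=agent)
    replay = b.make_replay_buffer(cal_rec, default_calibration.r_beta_hz)
    return prof, sched, rec, markers, default_calibration, replay


class TestRunTrial:
    def test_update_count_for_4p5s_precue(self, nf_setup):
        _, sched, rec, markers, cal, _ = nf_setup
        pc = next(m for m in markers if m.label == "precue" and m.trial_index == 5)
        log = b.run_trial(rec, cal, "left", "real",
                          precue_onset_s=pc.time_s, precue_s=4.5)
        assert len(log.d_beta_series) == 18
        assert len(log.bar.step_log) == 18

    def test_desync_agent_drives_bar_left(self, nf_setup):
        _, sched, rec, markers, cal, _ = nf_setup
        pcs = {m.trial_index: m.time_s for m in markers if m.label == "precue"}
        finals = []
        for t in [t for t in sched.analyzable if t.nf_direction == "left"][:20]:
            log = b.run_trial(rec, cal, "left", "real",
                              precue_onset_s=pcs[t.index], precue_s=t.precue_s)
            finals.append(log.final_position_px)
        assert np.mean(finals) < 0
        assert np.mean(np.array(finals) < 0) >= 0.8

    def test_sham_trajectory_independent_of_live_stream(self, nf_setup):
        """Permuting the live stream leaves sham-mode bar motion unchanged."""
        _, _, rec, markers, cal, _ = nf_setup
        values = np.linspace(100, 200, 60)
        log1 = b.run_trial(None, cal, "left", "sham",
                           ReplayBuffer(values.copy()), precue_s=4.5)
        log2 = b.run_trial(None, cal, "left", "sham",
                           ReplayBuffer(values.copy()), precue_s=4.5)
        assert np.array_equal(log1.d_beta_series, log2.d_beta_series)
        assert log1.bar.step_log == log2.bar.step_log

    def test_sham_requires_buffer_and_real_requires_source(self, nf_setup):
        _, _, _, _, cal, _ = nf_setup
        with pytest.raises(ValueError):
            b.run_trial(None, cal, "left", "sham", None)
        with pytest.raises(ValueError):
            b.run_trial(None, cal, "left", "real", None)


class TestRunSession:
    def test_full_schedule_counts(self, nf_setup):
        prof, sched, rec, markers, cal, replay = nf_setup
        conds = b.make_condition_schedule(["P01"], seed=2)
        sess = b.run_session(rec, markers, cal, sched, conds, "P01", 1,
                             replay_buffer=replay)
        assert len(sess.trials) == 112
        assert len(sess.analyzable) == 108
        assert sess.status == "complete"

    def test_summary_does_not_reveal_condition(self, nf_setup):
        prof, sched, rec, markers, cal, replay = nf_setup
        conds = b.make_condition_schedule(["P01"], seed=2)
        sess = b.run_session(rec, markers, cal, sched, conds, "P01", 1,
                             replay_buffer=replay)
        assert "condition" not in sess.summary()
        assert set(sess.summary()) == {
            "participant_id", "session_index", "n_trials", "n_analyzable",
            "status",
        }

    def test_deterministic(self, nf_setup):
        prof, sched, rec, markers, cal, _ = nf_setup
        conds = b.ConditionSchedule({"P01": ("real", "sham")}, seed=0)
        s1 = b.run_session(rec, markers, cal, sched, conds, "P01", 1)
        s2 = b.run_session(rec, markers, cal, sched, conds, "P01", 1)
        assert all(
            np.array_equal(a.d_beta_series, c.d_beta_series)
            and a.final_position_px == c.final_position_px
            for a, c in zip(s1.trials, s2.trials)
        )

    def test_truncated_on_source_dropout(self, nf_setup):
        prof, sched, rec, markers, cal, _ = nf_setup
        conds = b.ConditionSchedule({"P01": ("real", "sham")}, seed=0)
        half = b.EegRecording(rec.data[: rec.n_samples // 2], rec.rate_hz)
        with pytest.warns(UserWarning, match="truncated"):
            sess = b.run_session(half, markers, cal, sched, conds, "P01", 1)
        assert sess.status.startswith("truncated")
        assert 0 < len(sess.trials) < 112


class TestConditionSchedule:
    def test_counterbalance_17(self):
        conds = b.make_condition_schedule([f"P{i:02d}" for i in range(17)], seed=3)
        orders = list(conds.assignments.values())
        n_real_first = sum(1 for o in orders if o == ("real", "sham"))
        assert {n_real_first, 17 - n_real_first} == {8, 9}

    def test_two_participants_one_of_each(self):
        for seed in range(5):
            conds = b.make_condition_schedule(["A", "B"], seed=seed)
            assert set(conds.assignments.values()) == {("real", "sham"),
                                                       ("sham", "real")}

    def test_deterministic_and_round_trips(self, tmp_path):
        from betanf.io import load_condition_schedule, save_condition_schedule

        a = b.make_condition_schedule(["A", "B", "C"], seed=9)
        c = b.make_condition_schedule(["A", "B", "C"], seed=9)
        assert a.assignments == c.assignments
        p = tmp_path / "conds.json"
        save_condition_schedule(p, a)
        assert load_condition_schedule(p).assignments == a.assignments
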