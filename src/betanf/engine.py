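"""The closed-loop neurofeedback controller.

At the start of each trial the on-screen bar is reset to center and the
trial baseline ``BL_beta`` is taken as the mean band power in the 2 s
preceding pre-cue onset.  During the pre-cue period the relative beta
change ``D_beta`` (current 500 ms window minus ``BL_beta``) is updated
every 250 ms and drives the bar: 20 px left when ``D_beta`` falls below
the desynchronization threshold, 20 px right when it exceeds the
synchronization threshold, otherwise 10 px back toward center (never
crossing it).  The bar freezes at imperative-cue onset.

Sham sessions run the identical algorithm, but the values are replayed
sequentially from the calibration-phase beta stream and baselined against
the replay's own ``BL_beta``, so bar motion is decoupled from the live
signal.  The double-blind machinery is a pre-generated condition schedule
(counterbalanced real/sham session pairs) that only the engine reads.

Outlier interpolation is deliberately NOT applied on this real-time path:
causal interpolation is ill-defined, and the cleaning step belongs to the
saved time courses analysed offline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import CalibrationResult
from .recording import EegRecording, EventMarker
from .spectral import STEP_S, WINDOW_S, BetaTimeseries, band_power, psd_window, sliding_beta_power
from .task import TrialSchedule

__all__ = [
    "BarState",
    "NfTrialLog",
    "SessionResult",
    "ConditionSchedule",
    "ReplayBuffer",
    "trial_baseline",
    "update_bar",
    "run_trial",
    "run_session",
    "make_condition_schedule",
    "make_replay_buffer",
    "STEP_PX",
    "RECENTER_PX",
    "SCREEN_HALF_WIDTH_PX",
]

STEP_PX = 20
RECENTER_PX = 10
SCREEN_HALF_WIDTH_PX = 400
#: number of 250 ms beta values consumed from the replay stream to form
#: the sham trial's own baseline (2 s of stream at 4 values/s)
REPLAY_BASELINE_VALUES = 8


@dataclass
class BarState:
    """Bar position (px; 0 = center, negative = left) plus its history."""

    position_px: int = 0
    step_log: list = field(default_factory=list)

    def log(self, time_s: float, d_beta: float, decision: str) -> None:
        self.step_log.append(
            {"time_s": time_s, "d_beta": d_beta, "decision": decision,
             "position_px": self.position_px}
        )


@dataclass
class NfTrialLog:
    """Per-250 ms record of one feedback trial (real or sham)."""

    trial_index: int
    condition: str
    instructed_direction: Optional[str]
    trial_type: Optional[str]
    practice: bool
    bl_beta: float
    update_times_s: np.ndarray
    d_beta_series: np.ndarray
    bar: BarState
    final_position_px: int
    rt_s: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "trial_index": self.trial_index,
            "condition": self.condition,
            "instructed_direction": self.instructed_direction,
            "trial_type": self.trial_type,
            "practice": self.practice,
            "bl_beta": self.bl_beta,
            "update_times_s": np.asarray(self.update_times_s).tolist(),
            "d_beta_series": np.asarray(self.d_beta_series).tolist(),
            "step_log": self.bar.step_log,
            "final_position_px": self.final_position_px,
            "rt_s": self.rt_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NfTrialLog":
        bar = BarState(position_px=d["final_position_px"],
                       step_log=list(d["step_log"]))
        return cls(
            trial_index=d["trial_index"], condition=d["condition"],
            instructed_direction=d["instructed_direction"],
            trial_type=d["trial_type"], practice=d["practice"],
            bl_beta=d["bl_beta"],
            update_times_s=np.asarray(d["update_times_s"]),
            d_beta_series=np.asarray(d["d_beta_series"]),
            bar=bar, final_position_px=d["final_position_px"],
            rt_s=d.get("rt_s"),
        )


@dataclass
class SessionResult:
    """All trial logs of one session.

    ``summary()`` intentionally omits the condition so that a session
    runner handling the result cannot unblind themselves; the condition
    stays inside the per-trial logs consumed only by the offline analysis.
    """

    participant_id: str
    session_index: int
    trials: list
    status: str = "complete"

    @property
    def analyzable(self) -> list:
        return [t for t in self.trials if not t.practice]

    def summary(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "session_index": self.session_index,
            "n_trials": len(self.trials),
            "n_analyzable": len(self.analyzable),
            "status": self.status,
        }


@dataclass
class ConditionSchedule:
    """Counterbalanced real/sham session orders, fixed before the study."""

    assignments: dict
    seed: int

    def condition_for(self, participant_id: str, session_index: int) -> str:
        return self.assignments[participant_id][session_index - 1]

    def to_dict(self) -> dict:
        return {"assignments": {k: list(v) for k, v in self.assignments.items()},
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionSchedule":
        return cls(
            assignments={k: tuple(v) for k, v in d["assignments"].items()},
            seed=d["seed"],
        )


def make_condition_schedule(
    participant_ids: Sequence[str], seed: int = 0
) -> ConditionSchedule:
    """Assign each participant a (real, sham) or (sham, real) session pair,
    balanced across participants to within one."""
    ids = list(participant_ids)
    if not ids:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(seed)
    n = len(ids)
    orders = [("real", "sham")] * (n // 2) + [("sham", "real")] * (n - n // 2)
    perm = rng.permutation(n)
    return ConditionSchedule(
        assignments={ids[i]: orders[perm[i]] for i in range(n)}, seed=seed
    )


class ReplayBuffer:
    """Sequential reader over the calibration-phase beta stream.

    Values are consumed in order across sham trials, preserving the
    stream's temporal statistics; on exhaustion the cursor wraps to the
    start with a logged notice.
    """

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=float)
        if self.values.size == 0:
            raise ValueError("replay buffer is empty")
        self.cursor = 0
        self.n_wraps = 0

    def draw(self, n: int) -> np.ndarray:
        out = np.empty(n)
        for i in range(n):
            if self.cursor >= self.values.size:
                self.cursor = 0
                self.n_wraps += 1
                warnings.warn("replay buffer exhausted; wrapping to start")
            out[i] = self.values[self.cursor]
            self.cursor += 1
        return out


def make_replay_buffer(
    calibration_recording: EegRecording, r_beta: tuple
) -> ReplayBuffer:
    """Replay source from a calibration recording's beta power stream."""
    stream = sliding_beta_power(calibration_recording, r_beta)
    return ReplayBuffer(stream.values)


def trial_baseline(beta_stream: BetaTimeseries, precue_onset_s: float) -> float:
    """Mean of the 250 ms-grid beta values timestamped within the 2 s
    preceding pre-cue onset.

    The online loop emits one value per 250 ms, so a 2 s baseline holds
    eight values; a value belongs to the baseline when its timestamp (the
    end of its analysis window) falls in ``(precue_onset - 2, precue_onset]``.
    """
    eps = 1e-9
    t = beta_stream.times_s
    mask = (t > precue_onset_s - 2.0 + eps) & (t <= precue_onset_s + eps)
    if not mask.any():
        raise ValueError(
            "beta stream does not cover the 2 s pre-pre-cue baseline"
        )
    return float(beta_stream.values[mask].mean())


def update_bar(
    state: BarState,
    d_beta: float,
    th_desync: float,
    th_sync: float,
    time_s: float = 0.0,
    half_width_px: int = SCREEN_HALF_WIDTH_PX,
) -> BarState:
    """One 250 ms feedback step: threshold comparison and bar move.

    Mutates and returns ``state``.  Left 20 px below the desync threshold,
    right 20 px above the sync threshold, otherwise 10 px toward center
    without overshooting it; position clamps at the screen edges.
    """
    if th_desync > th_sync:
        raise ValueError("th_desync must not exceed th_sync")
    p = state.position_px
    if d_beta < th_desync:
        p -= STEP_PX
        decision = "left"
    elif d_beta > th_sync:
        p += STEP_PX
        decision = "right"
    else:
        decision = "recenter"
        if p > 0:
            p = max(0, p - RECENTER_PX)
        elif p < 0:
            p = min(0, p + RECENTER_PX)
    state.position_px = int(np.clip(p, -half_width_px, half_width_px))
    state.log(time_s, d_beta, decision)
    return state


def _live_beta_value(rec: EegRecording, t_end: float, r_beta: tuple) -> float:
    psd = psd_window(rec.slice(t_end - WINDOW_S, t_end), rec.rate_hz)
    return band_power(psd, r_beta)


def run_trial(
    source: Optional[EegRecording],
    calibration: CalibrationResult,
    direction: Optional[str],
    mode: str,
    replay_buffer: Optional[ReplayBuffer] = None,
    *,
    precue_onset_s: float = 0.0,
    precue_s: float = 4.5,
    trial_index: int = 0,
    trial_type: Optional[str] = None,
    practice: bool = False,
    rt_s: Optional[float] = None,
) -> NfTrialLog:
    """One feedback trial: bar reset, baseline, then 250 ms update loop.

    Real mode computes ``D_beta`` causally from the live stream; sham mode
    consumes the next values from the replay buffer (its own baseline
    first), then applies the identical bar algorithm with the current
    session's thresholds.
    """
    n_updates = int(np.floor(precue_s / STEP_S + 1e-9))
    times = precue_onset_s + STEP_S * np.arange(1, n_updates + 1)
    r_beta = calibration.r_beta_hz

    if mode == "real":
        if source is None:
            raise ValueError("real mode requires a live EEG source")
        base_times = precue_onset_s - 2.0 + STEP_S * np.arange(1, 9)
        base_vals = np.array(
            [_live_beta_value(source, t, r_beta) for t in base_times]
        )
        stream = BetaTimeseries(times_s=base_times, values=base_vals,
                                band_hz=r_beta, alignment="precue")
        bl = trial_baseline(stream, precue_onset_s)
        values = np.array(
            [_live_beta_value(source, t, r_beta) for t in times]
        )
    elif mode == "sham":
        if replay_buffer is None:
            raise ValueError("sham mode requires a replay buffer")
        bl = float(replay_buffer.draw(REPLAY_BASELINE_VALUES).mean())
        values = replay_buffer.draw(n_updates)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    d_beta = values - bl
    bar = BarState()
    for t, d in zip(times, d_beta):
        update_bar(bar, float(d), calibration.th_desync, calibration.th_sync,
                   time_s=float(t))
    return NfTrialLog(
        trial_index=trial_index, condition=mode,
        instructed_direction=direction, trial_type=trial_type,
        practice=practice, bl_beta=bl, update_times_s=times,
        d_beta_series=d_beta, bar=bar,
        final_position_px=bar.position_px, rt_s=rt_s,
    )


def run_session(
    source: EegRecording,
    markers: Sequence[EventMarker],
    calibration: CalibrationResult,
    schedule: TrialSchedule,
    conditions: ConditionSchedule,
    participant_id: str,
    session_index: int,
    replay_buffer: Optional[ReplayBuffer] = None,
) -> SessionResult:
    """Execute every trial of a session under its (blinded) condition.

    The condition is read from the pre-generated schedule, never from the
    caller.  Practice trials run normally but are flagged and excluded
    from the analyzable set.  If the source ends mid-session the result is
    truncated with an explicit status.
    """
    condition = conditions.condition_for(participant_id, session_index)
    if condition == "sham" and replay_buffer is None:
        raise ValueError("sham session requires a calibration replay buffer")
    precues = {m.trial_index: m for m in markers if m.label == "precue"}
    rts = {m.trial_index: m.rt_s for m in markers if m.label == "response"}
    logs, status = [], "complete"
    for trial in schedule:
        m = precues.get(trial.index)
        end_t = m.time_s + trial.precue_s if m is not None else np.inf
        if m is None or source.index_of(end_t) > source.n_samples:
            status = f"truncated at trial {trial.index}: source dropout"
            warnings.warn(status)
            break
        logs.append(
            run_trial(
                source if condition == "real" else None,
                calibration, trial.nf_direction, condition, replay_buffer,
                precue_onset_s=m.time_s, precue_s=trial.precue_s,
                trial_index=trial.index, trial_type=trial.trial_type,
                practice=trial.practice, rt_s=rts.get(trial.index),
            )
        )
    return SessionResult(participant_id=participant_id,
                         session_index=session_index,
                         trials=logs, status=status)


def sham_decoupling_r(
    session: SessionResult, live: EegRecording, r_beta: tuple
) -> float:
    """Pearson r between the live beta signal and the bar's step sizes
    across all updates of a session — near zero for sham sessions, where
    bar motion is driven by the replayed stream instead."""
    live_vals, steps = [], []
    for log in session.trials:
        prev = 0
        for t, entry in zip(log.update_times_s, log.bar.step_log):
            live_vals.append(_live_beta_value(live, float(t), r_beta))
            steps.append(entry["position_px"] - prev)
            prev = entry["position_px"]
    live_vals = np.asarray(live_vals)
    steps = np.asarray(steps, dtype=float)
    if live_vals.std() == 0 or steps.std() == 0:
        return 0.0
    return float(np.corrcoef(live_vals, steps)[0, 1])
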