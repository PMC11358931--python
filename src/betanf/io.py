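"""Plain-text serialization of every artifact in the pipeline.

Recordings travel as a two-file delimited pair (samples: time, microvolts;
events: one row per marker with the trial fields), calibration results and
condition schedules as JSON, session logs as JSON-lines (one trial per
line), and schedules as TSV with a JSON header line carrying the seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationResult
from .engine import ConditionSchedule, NfTrialLog, SessionResult
from .recording import EegRecording, EventMarker
from .task import Trial, TrialSchedule

__all__ = [
    "save_recording", "load_recording",
    "save_markers", "load_markers",
    "save_calibration", "load_calibration",
    "save_session_log", "load_session_log",
    "save_condition_schedule", "load_condition_schedule",
    "save_schedule", "load_schedule",
]


def save_recording(path, recording: EegRecording) -> None:
    df = pd.DataFrame({"time_s": recording.times(), "uV": recording.data})
    with open(path, "w") as f:
        f.write(f"# rate_hz={recording.rate_hz} channel={recording.channel}\n")
        df.to_csv(f, sep="\t", index=False, float_format="%.6f")


def load_recording(path) -> EegRecording:
    with open(path) as f:
        header = f.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        df = pd.read_csv(f, sep="\t")
    return EegRecording(
        data=df["uV"].to_numpy(),
        rate_hz=float(meta["rate_hz"]),
        start_time_s=float(df["time_s"].iloc[0]),
        channel=meta.get("channel", "C3-Cz"),
    )


_MARKER_COLS = ["time_s", "label", "trial_index", "trial_type",
                "nf_direction", "condition", "practice", "rt_s"]


def save_markers(path, markers: Sequence[EventMarker]) -> None:
    df = pd.DataFrame([{c: getattr(m, c) for c in _MARKER_COLS} for m in markers])
    df.to_csv(path, sep="\t", index=False)


def load_markers(path) -> list:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            EventMarker(
                time_s=float(row.time_s),
                label=str(row.label),
                trial_index=int(row.trial_index),
                trial_type=None if pd.isna(row.trial_type) else str(row.trial_type),
                nf_direction=(
                    None if pd.isna(row.nf_direction) else str(row.nf_direction)
                ),
                condition=None if pd.isna(row.condition) else str(row.condition),
                practice=bool(row.practice),
                rt_s=None if pd.isna(row.rt_s) else float(row.rt_s),
            )
        )
    return out


def save_calibration(path, result: CalibrationResult) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))


def load_calibration(path) -> CalibrationResult:
    return CalibrationResult.from_dict(json.loads(Path(path).read_text()))


def save_session_log(path, session: SessionResult) -> None:
    with open(path, "w") as f:
        f.write(json.dumps({"header": session.summary()}) + "\n")
        for log in session.trials:
            f.write(json.dumps(log.to_dict()) + "\n")


def load_session_log(path) -> SessionResult:
    with open(path) as f:
        header = json.loads(f.readline())["header"]
        trials = [NfTrialLog.from_dict(json.loads(line)) for line in f if line.strip()]
    return SessionResult(
        participant_id=header["participant_id"],
        session_index=header["session_index"],
        trials=trials,
        status=header["status"],
    )


def save_condition_schedule(path, schedule: ConditionSchedule) -> None:
    Path(path).write_text(json.dumps(schedule.to_dict(), indent=2))


def load_condition_schedule(path) -> ConditionSchedule:
    return ConditionSchedule.from_dict(json.loads(Path(path).read_text()))


def save_schedule(path, schedule: TrialSchedule) -> None:
    with open(path, "w") as f:
        f.write(json.dumps({"kind": schedule.kind, "seed": schedule.seed,
                            "rate_hz": schedule.rate_hz}) + "\n")
        schedule.to_frame().to_csv(f, sep="\t", index=False)


def load_schedule(path) -> TrialSchedule:
    with open(path) as f:
        meta = json.loads(f.readline())
        df = pd.read_csv(f, sep="\t")
    trials = [
        Trial(
            index=int(r.trial_index),
            trial_type=str(r.trial_type),
            nf_direction=None if pd.isna(r.nf_direction) else str(r.nf_direction),
            fixation_s=float(r.fixation_s),
            precue_s=float(r.precue_s),
            ic_s=float(r.ic_s),
            practice=bool(r.practice),
            block=int(r.block),
        )
        for _, r in df.iterrows()
    ]
    return TrialSchedule(trials=trials, kind=meta["kind"], seed=meta["seed"],
                         rate_hz=meta["rate_hz"])
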