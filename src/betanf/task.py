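"""Go/No-go trial schedules, response classification, and behavioral
summaries.

Protocol timing per trial: a fixation cross (2000 ms), a pre-cue bar
(4250-5000 ms with 750 ms uniform jitter; this is the neurofeedback
period), and an imperative cue — green Go or red No-go — on screen for
4000 ms.  Correct Go responses fall within 100-800 ms of the imperative
cue.  The calibration run has 32 trials (16 Go / 16 No-go, no feedback
direction); the neurofeedback run has 84 Go + 24 No-go analyzable trials
plus 4 practice trials in six blocks, with the instructed bar direction
balanced left/right within each trial type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trial",
    "TrialSchedule",
    "TrialOutcome",
    "build_calibration_schedule",
    "build_nf_schedule",
    "classify_response",
    "summarize_behavior",
    "FIXATION_S",
    "IC_S",
    "PRECUE_RANGE_S",
    "RT_MIN_S",
    "RT_MAX_S",
]

FIXATION_S = 2.0
IC_S = 4.0
PRECUE_RANGE_S = (4.25, 5.0)
RT_MIN_S = 0.1
RT_MAX_S = 0.8


@dataclass
class Trial:
    index: int
    trial_type: str                 # "go" | "nogo"
    nf_direction: Optional[str]     # "left" | "right" | None
    fixation_s: float = FIXATION_S
    precue_s: float = 4.5
    ic_s: float = IC_S
    practice: bool = False
    block: int = 0

    @property
    def duration_s(self) -> float:
        return self.fixation_s + self.precue_s + self.ic_s


@dataclass
class TrialSchedule:
    trials: list
    kind: str                       # "calibration" | "nf"
    seed: Optional[int] = None
    rate_hz: float = 500.0

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def analyzable(self) -> list:
        return [t for t in self.trials if not t.practice]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": [t.index for t in self.trials],
                "trial_type": [t.trial_type for t in self.trials],
                "nf_direction": [t.nf_direction for t in self.trials],
                "fixation_s": [t.fixation_s for t in self.trials],
                "precue_s": [t.precue_s for t in self.trials],
                "ic_s": [t.ic_s for t in self.trials],
                "practice": [t.practice for t in self.trials],
                "block": [t.block for t in self.trials],
            }
        )


@dataclass
class TrialOutcome:
    trial_index: int
    trial_type: str
    rt_s: Optional[float]
    classification: str
    nf_direction: Optional[str] = None
    condition: Optional[str] = None


def _jitter(rng: np.random.Generator) -> float:
    lo, hi = PRECUE_RANGE_S
    return float(rng.uniform(lo, hi))


def build_calibration_schedule(seed: int = 0) -> TrialSchedule:
    """32-trial calibration run: 16 Go / 16 No-go, seeded uniform shuffle,
    no feedback direction."""
    rng = np.random.default_rng(seed)
    types = ["go"] * 16 + ["nogo"] * 16
    rng.shuffle(types)
    trials = [
        Trial(index=i, trial_type=tt, nf_direction=None,
              precue_s=_jitter(rng), block=0)
        for i, tt in enumerate(types)
    ]
    return TrialSchedule(trials=trials, kind="calibration", seed=seed)


def build_nf_schedule(seed: int = 0) -> TrialSchedule:
    """Neurofeedback run: 84 Go + 24 No-go analyzable trials plus 4
    practice trials, six blocks of 18 analyzable trials.

    The instructed direction is balanced within each trial type
    (42 left / 42 right Go; 12 / 12 No-go); practice trials (2 Go left,
    1 Go right, 1 No-go) are prepended to block 1 and flagged.
    """
    rng = np.random.default_rng(seed)
    pool = (
        [("go", "left")] * 42 + [("go", "right")] * 42
        + [("nogo", "left")] * 12 + [("nogo", "right")] * 12
    )
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]
    practice = [("go", "left"), ("go", "right"), ("go", "left"), ("nogo", "right")]
    trials: list = []
    idx = 0
    for tt, d in practice:
        trials.append(Trial(index=idx, trial_type=tt, nf_direction=d,
                            precue_s=_jitter(rng), practice=True, block=1))
        idx += 1
    for j, (tt, d) in enumerate(pool):
        trials.append(Trial(index=idx, trial_type=tt, nf_direction=d,
                            precue_s=_jitter(rng), block=j // 18 + 1))
        idx += 1
    return TrialSchedule(trials=trials, kind="nf", seed=seed)


def classify_response(trial_type: str, rt_s: Optional[float]) -> TrialOutcome:
    """Classify one trial's behavioral outcome.

    Go trials: ``correct_go`` for 100 ms <= RT <= 800 ms, ``too_fast``
    below, ``too_slow`` above, ``miss`` with no response.  No-go trials:
    any response is a ``commission_error``, none is a
    ``correct_rejection``.
    """
    if trial_type not in ("go", "nogo"):
        raise ValueError(f"unknown trial type {trial_type!r}")
    if rt_s is not None and rt_s < 0:
        raise ValueError(f"negative reaction time {rt_s}")
    if trial_type == "go":
        if rt_s is None:
            cls = "miss"
        elif rt_s < RT_MIN_S:
            cls = "too_fast"
        elif rt_s > RT_MAX_S:
            cls = "too_slow"
        else:
            cls = "correct_go"
    else:
        cls = "correct_rejection" if rt_s is None else "commission_error"
    return TrialOutcome(trial_index=-1, trial_type=trial_type,
                        rt_s=rt_s, classification=cls)


_GO_ERRORS = ("too_slow", "too_fast", "miss")


def summarize_behavior(
    outcomes: Sequence[TrialOutcome],
    grouping: Sequence[str] = ("condition", "nf_direction"),
) -> pd.DataFrame:
    """Five-panel behavioral summary per group (condition x direction).

    Panels: mean RT over correct Go trials (all errors taken out); mean
    error count per Go trial; mean error count per No-go trial; mean
    timing of Go errors (too-slow responses, complete misses taken out);
    mean timing of No-go errors (commission responses).  Groups with no
    qualifying trials get an explicit null cell.
    """
    df = pd.DataFrame(
        {
            "trial_index": [o.trial_index for o in outcomes],
            "trial_type": [o.trial_type for o in outcomes],
            "rt_s": [o.rt_s for o in outcomes],
            "classification": [o.classification for o in outcomes],
            "nf_direction": [o.nf_direction for o in outcomes],
            "condition": [o.condition for o in outcomes],
        }
    )
    rows = []
    for keys, g in df.groupby(list(grouping), dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        go = g[g.trial_type == "go"]
        nogo = g[g.trial_type == "nogo"]
        correct = go[go.classification == "correct_go"]
        go_err = go[go.classification.isin(_GO_ERRORS)]
        too_slow = go[go.classification == "too_slow"]
        commission = nogo[nogo.classification == "commission_error"]
        rows.append(
            dict(zip(grouping, keys))
            | {
                "go_rt_mean_s": correct.rt_s.mean() if len(correct) else np.nan,
                "go_error_rate": len(go_err) / len(go) if len(go) else np.nan,
                "nogo_error_rate": (
                    len(commission) / len(nogo) if len(nogo) else np.nan
                ),
                "go_error_timing_s": (
                    too_slow.rt_s.mean() if len(too_slow) else np.nan
                ),
                "nogo_error_timing_s": (
                    commission.rt_s.mean() if len(commission) else np.nan
                ),
                "n_go": len(go),
                "n_nogo": len(nogo),
            }
        )
    return pd.DataFrame(rows)
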