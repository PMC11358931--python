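"""Core in-memory containers for the single-channel EEG stream.

The whole protocol runs on one bipolar derivation (C3 referenced to Cz)
sampled at 500 Hz, so the carrier type is deliberately minimal: a 1-D
float array in microvolts plus a sampling rate.  Event markers carry the
trial-protocol metadata (phase onsets, trial type, instructed direction,
responses) that every downstream stage keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["EegRecording", "EventMarker", "Epoch"]


@dataclass
class EegRecording:
    """Uniformly sampled single-channel signal in microvolts."""

    data: np.ndarray
    rate_hz: float
    start_time_s: float = 0.0
    channel: str = "C3-Cz"
    #: onset times of injected/known artifacts, if any (seconds)
    artifact_times_s: tuple = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("EegRecording holds a single channel (1-D array)")
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.rate_hz

    def index_of(self, t_s: float) -> int:
        """Sample index of absolute time ``t_s`` (rounded to the grid)."""
        return int(round((t_s - self.start_time_s) * self.rate_hz))

    def slice(self, t0_s: float, t1_s: float) -> np.ndarray:
        """Samples covering [t0, t1); raises if outside the recording."""
        i0, i1 = self.index_of(t0_s), self.index_of(t1_s)
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise ValueError(
                f"window [{t0_s}, {t1_s}) s outside recording "
                f"[{self.start_time_s}, {self.start_time_s + self.duration_s}) s"
            )
        return self.data[i0:i1]

    def copy_with(self, **changes) -> "EegRecording":
        return replace(self, **changes)


@dataclass
class EventMarker:
    """Timestamped protocol event.

    ``label`` is one of the phase onsets (``fixation``, ``precue``, ``ic``)
    or ``response``; response markers carry ``rt_s`` relative to IC onset.
    """

    time_s: float
    label: str
    trial_index: int
    trial_type: Optional[str] = None       # "go" | "nogo"
    nf_direction: Optional[str] = None     # "left" | "right" | None
    condition: Optional[str] = None        # "real" | "sham" | None
    practice: bool = False
    rt_s: Optional[float] = None


@dataclass
class Epoch:
    """Fixed-length slice of the recording, time-locked to an anchor event.

    ``t=0`` is the anchor.  ``precue_offset_s`` locates the pre-cue onset
    relative to the anchor (0 for pre-cue-anchored epochs, negative for
    IC-anchored epochs) so the per-trial baseline window — the 2 s preceding
    pre-cue onset — can be recovered from either anchoring.
    """

    samples: np.ndarray
    rate_hz: float
    window_s: tuple          # (t_lo, t_hi) relative to anchor
    anchor: str              # "ic" | "precue"
    trial_index: int
    trial_type: Optional[str] = None
    nf_direction: Optional[str] = None
    condition: Optional[str] = None
    rt_s: Optional[float] = None
    precue_offset_s: float = 0.0
    participant: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def index_of(self, t_rel_s: float) -> int:
        return int(round((t_rel_s - self.window_s[0]) * self.rate_hz))

    def slice(self, t0_rel_s: float, t1_rel_s: float) -> np.ndarray:
        i0, i1 = self.index_of(t0_rel_s), self.index_of(t1_rel_s)
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise ValueError(
                f"window [{t0_rel_s}, {t1_rel_s}) s outside epoch {self.window_s}"
            )
        return self.samples[i0:i1]
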