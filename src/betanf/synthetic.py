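"""Synthetic C3-Cz EEG with the statistical structure the protocol assumes.

The generator produces a beta oscillation at a configurable peak frequency
(14-31 Hz) riding on 1/f background noise, with the two canonical
movement-locked modulations on Go trials: a power drop 0-1 s after the
imperative cue (movement-related beta desynchronization, MRBD) and a power
overshoot 1-3 s after it (post-movement beta rebound, PMBR).  An optional
closed-loop "agent" scales beta power during the pre-cue neurofeedback
period according to the instructed direction, with configurable,
direction-asymmetric gain — setting ``sync_gain = 0`` reproduces the
empirical asymmetry in which beta can be suppressed on demand but not
raised.

The beta carrier is an amplitude-modulated sinusoid whose envelope steps
are smoothed with a 100 ms raised-cosine ramp; hard steps would create
spectral splatter that confounds PSD tests.  The background is white noise
spectrally shaped to a 1/f^a power law.  No alpha/mu rhythms, structured
blink artifacts, or multi-channel volume conduction are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .recording import EegRecording, EventMarker
from .task import TrialSchedule

__all__ = [
    "SyntheticProfile",
    "AgentModel",
    "generate_background",
    "synthesize_session",
    "inject_artifacts",
    "DEFAULT_PROFILE",
]

#: raised-cosine ramp length for envelope transitions (s)
RAMP_S = 0.1
#: quiet lead-in before the first trial, so that even the first trial's
#: pre-pre-cue baseline window lies inside the recording (s)
LEAD_IN_S = 5.0

MRBD_WINDOW = (0.0, 1.0)   # s post-IC
PMBR_WINDOW = (1.0, 3.0)   # s post-IC


@dataclass
class SyntheticProfile:
    """Generative parameters of one synthetic participant.

    Defaults: the beta peak sits at 21 Hz (the group-mean individual peak),
    MRBD suppresses 40% of beta power and the PMBR overshoots by 40%;
    the actual magnitudes of the two modulations are free parameters, set
    here to give the canonical biphasic envelope at comfortable SNR.
    """

    peak_beta_hz: float = 21.0
    baseline_beta_amp: float = 3.0       # µV
    mrbd_depth: float = 0.4              # fraction of power removed, [0, 1]
    pmbr_gain: float = 1.4               # power multiplier, >= 1
    noise_exponent: float = 1.0          # 1/f^a slope of background
    noise_amp: float = 1.0               # µV (SD of background)
    artifact_rate: float = 0.0           # expected artifacts per minute
    rt_mean_s: float = 0.49              # behavioral response model
    rt_sd_s: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not 14.0 <= self.peak_beta_hz <= 31.0:
            raise ValueError("peak_beta_hz must lie in [14, 31] Hz")
        if not 0.0 <= self.mrbd_depth <= 1.0:
            raise ValueError("mrbd_depth must lie in [0, 1]")
        if self.pmbr_gain < 1.0:
            raise ValueError("pmbr_gain must be >= 1")
        if min(self.baseline_beta_amp, self.noise_amp, self.artifact_rate) < 0:
            raise ValueError("amplitudes and rates must be non-negative")


DEFAULT_PROFILE = SyntheticProfile()


@dataclass
class AgentModel:
    """Closed-loop participant model acting during the pre-cue period.

    When instructed "left" the agent reduces beta power by ``desync_gain``
    (fractional); when instructed "right" it raises it by ``sync_gain``,
    both after a reaction lag.  The empirical finding that nobody could
    reliably raise beta is emulated with ``sync_gain = 0``.
    """

    profile: SyntheticProfile = field(default_factory=SyntheticProfile)
    desync_gain: float = 0.5
    sync_gain: float = 0.0
    lag_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.desync_gain <= 1.0:
            raise ValueError("desync_gain must lie in [0, 1]")
        if self.sync_gain < 0 or self.lag_s < 0:
            raise ValueError("sync_gain and lag_s must be non-negative")


def generate_background(
    duration_s: float,
    rate_hz: float,
    profile: SyntheticProfile,
    rng: Optional[np.random.Generator] = None,
) -> EegRecording:
    """1/f^a-coloured background noise of the requested length.

    White Gaussian noise is shaped in the frequency domain by f^(-a/2)
    (power goes as f^-a), the DC bin is zeroed, and the result is rescaled
    so its standard deviation equals ``noise_amp``.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and rate must be positive")
    n = int(round(duration_s * rate_hz))
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    if profile.noise_amp == 0:
        return EegRecording(data=np.zeros(n), rate_hz=rate_hz)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-profile.noise_exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    x *= profile.noise_amp / x.std()
    return EegRecording(data=x, rate_hz=rate_hz)


def _smooth_envelope(amp: np.ndarray, rate_hz: float) -> np.ndarray:
    """Raised-cosine smoothing of a piecewise-constant amplitude envelope."""
    m = int(round(RAMP_S * rate_hz))
    if m < 2:
        return amp
    kernel = sps.windows.hann(m)
    kernel /= kernel.sum()
    return np.convolve(amp, kernel, mode="same")


def synthesize_session(
    profile: SyntheticProfile,
    schedule: TrialSchedule,
    agent: Optional[AgentModel] = None,
    rate_hz: float = 500.0,
) -> tuple:
    """Generate one session's EEG stream and its event markers.

    The beta carrier holds baseline power except: on Go trials its power is
    scaled by ``1 - mrbd_depth`` during 0-1 s post-IC and by ``pmbr_gain``
    during 1-3 s post-IC; if an agent is given, pre-cue-period power is
    additionally scaled by ``1 - desync_gain`` ("left") or
    ``1 + sync_gain`` ("right") starting ``lag_s`` after pre-cue onset.
    Markers are emitted for every phase onset plus Go responses drawn from
    the profile's reaction-time model.  Artifacts are injected afterwards
    at ``profile.artifact_rate``.

    Returns ``(EegRecording, list[EventMarker])``; deterministic in
    ``(profile, schedule, agent)``.
    """
    if rate_hz < 2 * 31.0:
        raise ValueError("sampling rate must exceed twice the beta band edge")
    rng = np.random.default_rng(profile.seed)

    total_s = LEAD_IN_S + sum(t.duration_s for t in schedule) + 2.0
    n = int(round(total_s * rate_hz))
    power_factor = np.ones(n)
    markers: list = []

    def _span(t0: float, t1: float) -> slice:
        return slice(int(round(t0 * rate_hz)), int(round(t1 * rate_hz)))

    t = LEAD_IN_S
    for trial in schedule:
        t_fix, t_pc = t, t + trial.fixation_s
        t_ic = t_pc + trial.precue_s
        meta = dict(trial_index=trial.index, trial_type=trial.trial_type,
                    nf_direction=trial.nf_direction, practice=trial.practice)
        markers.append(EventMarker(time_s=t_fix, label="fixation", **meta))
        markers.append(EventMarker(time_s=t_pc, label="precue", **meta))
        markers.append(EventMarker(time_s=t_ic, label="ic", **meta))
        if trial.trial_type == "go":
            power_factor[_span(t_ic + MRBD_WINDOW[0], t_ic + MRBD_WINDOW[1])] *= (
                1.0 - profile.mrbd_depth
            )
            power_factor[_span(t_ic + PMBR_WINDOW[0], t_ic + PMBR_WINDOW[1])] *= (
                profile.pmbr_gain
            )
            rt = float(np.clip(rng.normal(profile.rt_mean_s, profile.rt_sd_s),
                               0.12, 0.78))
            markers.append(EventMarker(time_s=t_ic + rt, label="response",
                                       rt_s=rt, **meta))
        if agent is not None and trial.nf_direction in ("left", "right"):
            gain = (1.0 - agent.desync_gain if trial.nf_direction == "left"
                    else 1.0 + agent.sync_gain)
            power_factor[_span(t_pc + agent.lag_s, t_ic)] *= gain
        t = t_ic + trial.ic_s

    amp = profile.baseline_beta_amp * np.sqrt(power_factor)
    amp = _smooth_envelope(amp, rate_hz)
    phase = rng.uniform(0, 2 * np.pi)
    tt = np.arange(n) / rate_hz
    beta = amp * np.sin(2 * np.pi * profile.peak_beta_hz * tt + phase)

    background = generate_background(total_s, rate_hz, profile, rng=rng)
    rec = EegRecording(data=beta + background.data[:n], rate_hz=rate_hz)
    if profile.artifact_rate > 0:
        rec = inject_artifacts(rec, profile.artifact_rate,
                               seed=int(rng.integers(2**31)))
    return rec, markers


def inject_artifacts(
    recording: EegRecording, artifact_rate: float, seed: int = 0
) -> EegRecording:
    """Add high-amplitude transient deflections at Poisson times.

    Each artifact is a Hann-shaped deflection of 50-200 ms whose peak is
    10-15x the signal SD, with random sign.  The number of artifacts is
    Poisson with mean ``artifact_rate`` per minute; onset times are
    recorded on the returned copy's ``artifact_times_s``.
    """
    if artifact_rate < 0:
        raise ValueError("artifact_rate must be non-negative")
    if artifact_rate == 0:
        return recording
    rng = np.random.default_rng(seed)
    fs = recording.rate_hz
    n_art = rng.poisson(artifact_rate * recording.duration_s / 60.0)
    data = recording.data.copy()
    scale = max(float(recording.data.std()), 1.0)
    times = []
    for _ in range(n_art):
        dur = rng.uniform(0.05, 0.2)
        onset = rng.uniform(0.0, recording.duration_s - dur)
        m = int(round(dur * fs))
        i0 = int(round(onset * fs))
        peak = rng.uniform(10.0, 15.0) * scale * rng.choice([-1.0, 1.0])
        data[i0:i0 + m] += peak * sps.windows.hann(m)
        times.append(recording.start_time_s + onset)
    return recording.copy_with(
        data=data, artifact_times_s=tuple(sorted(times))
    )
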