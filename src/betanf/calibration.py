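"""Individualized beta calibration from a 32-trial Go/No-go run.

From the correct Go trials of the calibration run this module derives the
participant-specific beta peak ``fmax`` (the frequency of maximal
modulation between the post-movement rebound and movement-related
desynchronization spectra, searched over the nominal 14-31 Hz band), the
individual beta range ``fmax +- 5 Hz`` clipped to [14, 31], and the two
feedback thresholds: the per-trial medians of baselined band power in the
MRBD (0-1 s post-IC) and PMBR (1-3 s post-IC) windows.  A QC step
confirms the canonical biphasic beta signature (desynchronization during
movement, rebound after it) before the result is trusted.

Windows longer than the 500 ms real-time primitive (the 1 s MRBD, 2 s
PMBR and 2 s baseline windows) are estimated as the mean of
non-overlapping 500 ms PSD tiles, keeping a single spectral primitive
across the real-time and offline paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .recording import EegRecording, EventMarker, Epoch
from .spectral import (
    BetaTimeseries,
    band_power,
    clean_outliers,
    psd_window,
    sliding_beta_power,
)

__all__ = [
    "AnalysisWindows",
    "CalibrationResult",
    "SignatureReport",
    "epoch_by_event",
    "compute_fmax_beta",
    "beta_range",
    "compute_thresholds",
    "verify_beta_signature",
    "calibrate",
    "NOMINAL_BAND",
    "MIN_CALIBRATION_TRIALS",
]

#: nominal beta band (Hz) searched for the individual peak
NOMINAL_BAND = (14.0, 31.0)
#: minimum number of correct Go trials for a usable calibration
MIN_CALIBRATION_TRIALS = 8
#: PSD tile length matching the real-time primitive (s)
TILE_S = 0.5


@dataclass(frozen=True)
class AnalysisWindows:
    """The protocol's fixed analysis windows (seconds, relative anchors)."""

    mrbd_window: tuple = (0.0, 1.0)       # post-IC
    pmbr_window: tuple = (1.0, 3.0)       # post-IC
    baseline_window_s: float = 2.0        # preceding pre-cue onset
    nominal_band: tuple = NOMINAL_BAND


WINDOWS = AnalysisWindows()


@dataclass
class CalibrationResult:
    """Participant-specific quantities driving the neurofeedback phase."""

    fmax_beta_hz: float
    r_beta_hz: tuple
    th_desync: float
    th_sync: float
    per_trial_mrbd: np.ndarray
    per_trial_pmbr: np.ndarray
    signature_ok: bool
    n_trials: int
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fmax_beta_hz": self.fmax_beta_hz,
            "r_beta_hz": list(self.r_beta_hz),
            "th_desync": self.th_desync,
            "th_sync": self.th_sync,
            "per_trial_mrbd": np.asarray(self.per_trial_mrbd).tolist(),
            "per_trial_pmbr": np.asarray(self.per_trial_pmbr).tolist(),
            "signature_ok": bool(self.signature_ok),
            "n_trials": self.n_trials,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(
            fmax_beta_hz=d["fmax_beta_hz"],
            r_beta_hz=tuple(d["r_beta_hz"]),
            th_desync=d["th_desync"],
            th_sync=d["th_sync"],
            per_trial_mrbd=np.asarray(d["per_trial_mrbd"]),
            per_trial_pmbr=np.asarray(d["per_trial_pmbr"]),
            signature_ok=d["signature_ok"],
            n_trials=d["n_trials"],
            provenance=d.get("provenance", {}),
        )


@dataclass
class SignatureReport:
    """QC report confirming the biphasic movement-locked beta pattern."""

    timecourse: BetaTimeseries
    mrbd_present: bool
    pmbr_present: bool
    mean_mrbd_diff: float
    mean_pmbr_diff: float

    @property
    def ok(self) -> bool:
        return self.mrbd_present and self.pmbr_present


def epoch_by_event(
    recording: EegRecording,
    markers: Sequence[EventMarker],
    anchor: str,
    window_s: tuple,
) -> list:
    """Fixed-length epochs time-locked to every ``anchor`` marker.

    Trials whose window falls outside the recording are skipped with a
    warning; markers may arrive in any order (output is sorted by trial
    index).  Response markers supply each epoch's reaction time; pre-cue
    markers supply the pre-cue onset offset needed to locate the per-trial
    baseline window.
    """
    t_lo, t_hi = window_s
    anchors = sorted(
        (m for m in markers if m.label == anchor), key=lambda m: m.trial_index
    )
    if not anchors:
        raise ValueError(f"no {anchor!r} markers found")
    rts = {m.trial_index: m.rt_s for m in markers if m.label == "response"}
    precues = {m.trial_index: m.time_s for m in markers if m.label == "precue"}
    epochs = []
    for m in anchors:
        i0 = recording.index_of(m.time_s + t_lo)
        i1 = i0 + int(round((t_hi - t_lo) * recording.rate_hz))
        if i0 < 0 or i1 > recording.n_samples:
            warnings.warn(
                f"trial {m.trial_index}: epoch window outside recording; skipped"
            )
            continue
        pc = precues.get(m.trial_index)
        epochs.append(
            Epoch(
                samples=recording.data[i0:i1],
                rate_hz=recording.rate_hz,
                window_s=(t_lo, t_hi),
                anchor=anchor,
                trial_index=m.trial_index,
                trial_type=m.trial_type,
                nf_direction=m.nf_direction,
                condition=m.condition,
                rt_s=rts.get(m.trial_index),
                precue_offset_s=0.0 if pc is None else pc - m.time_s,
            )
        )
    if not epochs:
        raise ValueError("zero usable trials after epoching")
    return epochs


def _is_correct_go(ep: Epoch) -> bool:
    return (
        ep.trial_type == "go"
        and ep.rt_s is not None
        and 0.1 <= ep.rt_s <= 0.8
    )


def _tiled_psd(ep: Epoch, t0: float, t1: float) -> np.ndarray:
    """Mean one-sided PSD over non-overlapping 500 ms tiles of [t0, t1)."""
    n_tiles = int(round((t1 - t0) / TILE_S))
    spectra = []
    for k in range(n_tiles):
        seg = ep.slice(t0 + k * TILE_S, t0 + (k + 1) * TILE_S)
        spectra.append(psd_window(seg, ep.rate_hz).power)
    return np.mean(spectra, axis=0)


def _require_go_epochs(epochs: Sequence[Epoch]) -> list:
    go = [ep for ep in epochs if _is_correct_go(ep)]
    if len(go) < MIN_CALIBRATION_TRIALS:
        raise ValueError(
            f"calibration needs >= {MIN_CALIBRATION_TRIALS} correct Go "
            f"trials, got {len(go)}"
        )
    return go


def peak_frequency(freqs_hz: np.ndarray, values: np.ndarray,
                   band: tuple = NOMINAL_BAND) -> float:
    """Frequency of the maximum of ``values`` within ``band`` (inclusive);
    exact ties break toward the lower frequency."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = band
    mask = (freqs_hz >= lo - 1e-9) & (freqs_hz <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    sel = values[mask]
    return float(freqs_hz[mask][int(np.argmax(sel))])


def compute_fmax_beta(epochs: Sequence[Epoch]) -> float:
    """Frequency of maximal movement-locked beta modulation.

    Mean PSD is computed across correct Go trials in the MRBD and PMBR
    windows; the result is the 14-31 Hz frequency maximizing
    ``PSD_PMBR(f) - PSD_MRBD(f)`` (the rebound-minus-desynchronization
    contrast is positive at the modulated frequency whenever both
    phenomena exist).  Ties break toward the lower frequency.
    """
    go = _require_go_epochs(epochs)
    mrbd = np.mean([_tiled_psd(ep, *WINDOWS.mrbd_window) for ep in go], axis=0)
    pmbr = np.mean([_tiled_psd(ep, *WINDOWS.pmbr_window) for ep in go], axis=0)
    freqs = psd_window(go[0].slice(0.0, TILE_S), go[0].rate_hz).freqs_hz
    return peak_frequency(freqs, pmbr - mrbd, NOMINAL_BAND)


def beta_range(fmax: float) -> tuple:
    """Individual beta range: fmax +- 5 Hz, clipped to [14, 31] Hz."""
    lo, hi = NOMINAL_BAND
    if not lo <= fmax <= hi:
        raise ValueError(f"fmax {fmax} Hz outside nominal band {NOMINAL_BAND}")
    return (max(fmax - 5.0, lo), min(fmax + 5.0, hi))


@dataclass
class ThresholdResult:
    th_desync: float
    th_sync: float
    per_trial_mrbd: np.ndarray
    per_trial_pmbr: np.ndarray

    def __iter__(self):
        return iter((self.th_desync, self.th_sync))


def compute_thresholds(
    epochs: Sequence[Epoch], r_beta: tuple
) -> ThresholdResult:
    """Feedback thresholds: trial-median baselined band power.

    For each correct Go trial, mean band power over ``r_beta`` is computed
    in the MRBD window, the PMBR window, and the 2 s baseline preceding
    pre-cue onset; the thresholds are the medians across trials of
    (MRBD - baseline) and (PMBR - baseline).
    """
    go = _require_go_epochs(epochs)
    mrbd_d, pmbr_d = [], []
    for ep in go:
        pc = ep.precue_offset_s
        if pc - WINDOWS.baseline_window_s < ep.window_s[0]:
            raise ValueError(
                f"trial {ep.trial_index}: epoch lacks the 2 s pre-pre-cue "
                "baseline window"
            )
        freqs = psd_window(ep.slice(0.0, TILE_S), ep.rate_hz).freqs_hz
        lo, hi = r_beta
        mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        base = _tiled_psd(ep, pc - WINDOWS.baseline_window_s, pc)[mask].mean()
        mrbd = _tiled_psd(ep, *WINDOWS.mrbd_window)[mask].mean()
        pmbr = _tiled_psd(ep, *WINDOWS.pmbr_window)[mask].mean()
        mrbd_d.append(mrbd - base)
        pmbr_d.append(pmbr - base)
    mrbd_d = np.asarray(mrbd_d)
    pmbr_d = np.asarray(pmbr_d)
    return ThresholdResult(
        th_desync=float(np.median(mrbd_d)),
        th_sync=float(np.median(pmbr_d)),
        per_trial_mrbd=mrbd_d,
        per_trial_pmbr=pmbr_d,
    )


def verify_beta_signature(
    epochs: Sequence[Epoch], band: tuple = NOMINAL_BAND
) -> SignatureReport:
    """Confirm desynchronization-then-rebound around the imperative cue.

    Produces the outlier-cleaned mean beta time course across correct Go
    trials (time-locked to the IC on the 250 ms grid) plus two booleans:
    mean MRBD-window power below baseline, mean PMBR-window power above
    baseline.  A report is always produced; callers decide what to do
    with a failed signature.
    """
    go = [ep for ep in epochs if _is_correct_go(ep)]
    if not go:
        go = list(epochs)
    courses = []
    for ep in go:
        rec = EegRecording(
            data=ep.samples, rate_hz=ep.rate_hz, start_time_s=ep.window_s[0]
        )
        bt = sliding_beta_power(rec, band)
        courses.append(bt.values)
    mean_course = BetaTimeseries(
        times_s=bt.times_s, values=np.mean(courses, axis=0),
        band_hz=band, alignment="ic",
    )
    mean_course = clean_outliers(mean_course)

    mrbd_diffs, pmbr_diffs = [], []
    for ep in go:
        freqs = psd_window(ep.slice(0.0, TILE_S), ep.rate_hz).freqs_hz
        lo, hi = band
        mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        pc = ep.precue_offset_s
        base = _tiled_psd(ep, pc - WINDOWS.baseline_window_s, pc)[mask].mean()
        mrbd_diffs.append(_tiled_psd(ep, *WINDOWS.mrbd_window)[mask].mean() - base)
        pmbr_diffs.append(_tiled_psd(ep, *WINDOWS.pmbr_window)[mask].mean() - base)
    mean_mrbd = float(np.mean(mrbd_diffs))
    mean_pmbr = float(np.mean(pmbr_diffs))

    def _one_sided(diffs, alternative) -> bool:
        # presence = consistent per-trial deflection, not a noisy mean sign
        diffs = np.asarray(diffs)
        if np.all(diffs == 0):
            return False
        from scipy.stats import wilcoxon

        return bool(wilcoxon(diffs, alternative=alternative).pvalue < 0.05)

    return SignatureReport(
        timecourse=mean_course,
        mrbd_present=_one_sided(mrbd_diffs, "less"),
        pmbr_present=_one_sided(pmbr_diffs, "greater"),
        mean_mrbd_diff=mean_mrbd,
        mean_pmbr_diff=mean_pmbr,
    )


#: IC-anchored epoch window wide enough to include the pre-trial baseline
CALIBRATION_EPOCH_S = (-7.5, 4.0)


def calibrate(
    recording: EegRecording,
    markers: Sequence[EventMarker],
    provenance: Optional[dict] = None,
) -> CalibrationResult:
    """Full calibration pipeline on one 32-trial Go/No-go run."""
    epochs = epoch_by_event(recording, markers, "ic", CALIBRATION_EPOCH_S)
    go = _require_go_epochs(epochs)
    fmax = compute_fmax_beta(go)
    r_beta = beta_range(fmax)
    thr = compute_thresholds(go, r_beta)
    sig = verify_beta_signature(go, NOMINAL_BAND)
    return CalibrationResult(
        fmax_beta_hz=fmax,
        r_beta_hz=r_beta,
        th_desync=thr.th_desync,
        th_sync=thr.th_sync,
        per_trial_mrbd=thr.per_trial_mrbd,
        per_trial_pmbr=thr.per_trial_pmbr,
        signature_ok=sig.ok,
        n_trials=len(go),
        provenance=provenance or {},
    )
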