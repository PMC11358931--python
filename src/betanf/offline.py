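"""Offline pipeline: epoching, individualized band-pass, artifact
handling, time-frequency decomposition, relative beta, and the
statistical battery.

Relative beta for a feedback trial is the ratio of band power during the
4 s neurofeedback period (after pre-cue onset) to band power during the
2 s baseline before it, expressed in decibels — 0 dB means no change, and
negative values mean the participant suppressed beta.  The group-level
battery mirrors a within-subject sham-controlled design: signed-rank
tests on per-second beta time courses, per-participant reaction-time /
relative-beta correlations in each (condition x direction) cell, and a
one-way repeated-measures ANOVA over the four cells with Tukey-corrected
pairwise contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

from .recording import Epoch
from .spectral import band_power, psd_window

__all__ = [
    "RelativeBeta",
    "StatResult",
    "TimeFreqMap",
    "bandpass_individual",
    "reject_artifacts",
    "stft_timefreq",
    "relative_beta",
    "beta_timecourse_table",
    "paired_signed_rank",
    "rt_beta_correlation",
    "condition_anova",
]

TILE_S = 0.5
TIMEPOINTS_S = (-2, -1, 0, 1, 2, 3, 4)
CELLS = (("real", "left"), ("real", "right"), ("sham", "left"), ("sham", "right"))


@dataclass
class RelativeBeta:
    """Feedback-period beta power relative to the trial baseline (dB)."""

    value_db: float
    trial_index: int
    condition: Optional[str] = None
    nf_direction: Optional[str] = None
    rt_s: Optional[float] = None


@dataclass
class StatResult:
    statistic: float
    statistic_name: str          # "Z" | "F" | "t" | "r"
    p_value: float
    label: str = ""
    df: Optional[tuple] = None
    correction: Optional[str] = None
    degenerate: bool = False
    n: Optional[int] = None


@dataclass
class TimeFreqMap:
    """Power per (frequency, time) cell from 2 s Hann segments at 1 s hop."""

    times_s: np.ndarray           # segment centers, epoch-relative
    freqs_hz: np.ndarray          # 1 Hz grid
    power: np.ndarray             # (n_freqs, n_times)


def bandpass_individual(
    epochs: Sequence[Epoch], r_beta: tuple, numtaps: int = 751
) -> list:
    """Zero-phase FIR band-pass at the individual beta range.

    A linear-phase FIR (Hamming-windowed ``firwin``) applied forward and
    backward; no notch filter is used, the band sitting well below mains
    interference.  Returns new epochs; input is untouched.
    """
    lo, hi = r_beta
    out = []
    for ep in epochs:
        nyq = ep.rate_hz / 2.0
        if hi >= nyq:
            raise ValueError(f"band edge {hi} Hz at or above Nyquist {nyq} Hz")
        taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=ep.rate_hz)
        filtered = sps.filtfilt(taps, [1.0], ep.samples)
        new = Epoch(**{**ep.__dict__, "samples": filtered})
        out.append(new)
    return out


def reject_artifacts(
    epochs: Sequence[Epoch],
    amplitude_uv: float = 150.0,
    variance_mult: float = 5.0,
) -> tuple:
    """Automated artifact rejection with explicit, deterministic rules.

    Drops epochs whose peak-to-peak amplitude exceeds ``amplitude_uv`` or
    whose variance exceeds ``variance_mult`` times the median epoch
    variance.  Returns ``(retained, rejection_log)``; the log lists every
    dropped trial with the rule that fired.
    """
    if amplitude_uv <= 0 or variance_mult <= 0:
        raise ValueError("rejection thresholds must be positive")
    variances = np.array([ep.samples.var() for ep in epochs])
    med_var = np.median(variances)
    retained, log = [], []
    for ep, v in zip(epochs, variances):
        ptp = float(np.ptp(ep.samples))
        if ptp > amplitude_uv:
            log.append({"trial_index": ep.trial_index, "rule": "amplitude",
                        "value": ptp, "threshold": amplitude_uv})
        elif v > variance_mult * med_var:
            log.append({"trial_index": ep.trial_index, "rule": "variance",
                        "value": float(v),
                        "threshold": float(variance_mult * med_var)})
        else:
            retained.append(ep)
    if not retained:
        raise ValueError("artifact rejection dropped every epoch")
    return retained, log


def stft_timefreq(
    epoch: Epoch, window_s: float = 2.0, overlap: float = 0.5
) -> TimeFreqMap:
    """Short-time Fourier power map: 2 s Hann segments, 50% overlap.

    The native 0.5 Hz bins of a 2 s window are averaged in adjacent pairs
    onto a 1 Hz grid (out[k] pools the bins at k-0.5 and k Hz), which
    stabilizes per-bin estimates.  Power is raw squared magnitude, on the
    same scale as the rest of the pipeline.
    """
    fs = epoch.rate_hz
    nwin = int(round(window_s * fs))
    hop = int(round(nwin * (1.0 - overlap)))
    if epoch.n_samples < nwin:
        raise ValueError(
            f"epoch of {epoch.n_samples / fs:g} s shorter than the "
            f"{window_s:g} s STFT window"
        )
    taper = sps.windows.hann(nwin, sym=False)
    starts = np.arange(0, epoch.n_samples - nwin + 1, hop)
    native = np.empty((nwin // 2 + 1, starts.size))
    for j, s in enumerate(starts):
        seg = sps.detrend(epoch.samples[s:s + nwin], type="linear")
        native[:, j] = np.abs(np.fft.rfft(seg * taper)) ** 2
    native_freqs = np.fft.rfftfreq(nwin, 1.0 / fs)
    n_out = (native.shape[0] - 1) // 2
    power = 0.5 * (native[1:2 * n_out:2] + native[2:2 * n_out + 1:2])
    freqs = native_freqs[2:2 * n_out + 1:2]
    times = epoch.window_s[0] + (starts + nwin / 2.0) / fs
    return TimeFreqMap(times_s=times, freqs_hz=freqs, power=power)


def relative_beta(epoch: Epoch, r_beta: tuple) -> RelativeBeta:
    """dB ratio of feedback-period to baseline beta power for one trial.

    Requires a pre-cue-anchored epoch with 2 s of pre-history; band power
    in the 4 s feedback period [0, 4] s and the 2 s baseline [-2, 0] s is
    the mean of non-overlapping 500 ms PSD tiles.
    """
    if epoch.anchor != "precue":
        raise ValueError("relative_beta expects pre-cue-anchored epochs")
    if epoch.window_s[0] > -2.0 or epoch.window_s[1] < 4.0:
        raise ValueError("epoch must span [-2, 4] s around pre-cue onset")

    def _mean_power(t0: float, t1: float) -> float:
        vals = []
        for k in range(int(round((t1 - t0) / TILE_S))):
            seg = epoch.slice(t0 + k * TILE_S, t0 + (k + 1) * TILE_S)
            vals.append(band_power(psd_window(seg, epoch.rate_hz), r_beta))
        return float(np.mean(vals))

    nf = _mean_power(0.0, 4.0)
    base = _mean_power(-2.0, 0.0)
    if base <= 0:
        raise ValueError("zero baseline beta power; dB ratio undefined")
    return RelativeBeta(
        value_db=float(10.0 * np.log10(nf / base)),
        trial_index=epoch.trial_index,
        condition=epoch.condition,
        nf_direction=epoch.nf_direction,
        rt_s=epoch.rt_s,
    )


def _timepoint_power(ep: Epoch, t: float, band: tuple) -> float:
    """Mean band power of the 500 ms windows spanning integer second t,
    using whichever of [t-0.5, t] and [t, t+0.5] the epoch contains."""
    vals = []
    for t0, t1 in ((t - TILE_S, t), (t, t + TILE_S)):
        if t0 >= ep.window_s[0] - 1e-9 and t1 <= ep.window_s[1] + 1e-9:
            seg = ep.slice(t0, t1)
            vals.append(band_power(psd_window(seg, ep.rate_hz), band))
    if not vals:
        raise ValueError(f"timepoint {t} s outside epoch window {ep.window_s}")
    return float(np.mean(vals))


def beta_timecourse_table(
    epochs: Sequence[Epoch],
    band,
    grouping: Sequence[str] = ("condition", "nf_direction"),
    timepoints_s: Sequence[float] = TIMEPOINTS_S,
) -> pd.DataFrame:
    """Group mean/SD beta power at integer-second timepoints.

    ``band`` is either one (lo, hi) tuple or a dict mapping participant id
    to that participant's individual range.  Trial values are averaged
    within participant, then the mean and SD across participants is
    reported per group and timepoint; a single-participant group gets a
    null SD.
    """
    rows = []
    for ep in epochs:
        b = band[ep.participant] if isinstance(band, dict) else band
        for t in timepoints_s:
            rows.append(
                {
                    "participant": ep.participant,
                    "condition": ep.condition,
                    "nf_direction": ep.nf_direction,
                    "timepoint_s": t,
                    "power": _timepoint_power(ep, float(t), b),
                }
            )
    df = pd.DataFrame(rows)
    per_part = (
        df.groupby(["participant", *grouping, "timepoint_s"], dropna=False)
        .power.mean()
        .reset_index()
    )
    out = (
        per_part.groupby([*grouping, "timepoint_s"], dropna=False)
        .power.agg(mean="mean", sd="std", n_participants="count")
        .reset_index()
    )
    return out


def paired_signed_rank(x, y, label: str = "") -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  The p-value uses the exact null
    distribution when sample size permits and no ties are present
    (matching exact enumeration), otherwise the normal approximation with
    tie correction; the reported statistic is always the tie-corrected
    normal-approximation Z, signed so that Z < 0 means x < y on average.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return StatResult(statistic=np.nan, statistic_name="Z", p_value=np.nan,
                          label=label, degenerate=True, n=0)
    ranks = sstats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts) / 48.0).sum())
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_pos - mu) / sigma if sigma > 0 else np.nan
    if sigma == 0:
        return StatResult(statistic=np.nan, statistic_name="Z", p_value=np.nan,
                          label=label, degenerate=True, n=n)
    res = sstats.wilcoxon(d, zero_method="wilcox", method="auto")
    return StatResult(statistic=float(z), statistic_name="Z",
                      p_value=float(res.pvalue), label=label, n=n)


def rt_beta_correlation(
    trials: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Per-participant correlation between reaction time and relative beta
    in each (condition x direction) cell.

    ``trials`` needs columns participant, condition, nf_direction, rt_s,
    relative_beta (correct Go trials only).  Cells with fewer than 5
    trials or zero variance are null and flagged.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    corr = sstats.pearsonr if method == "pearson" else sstats.spearmanr
    rows = []
    for (part, cond, d), g in trials.groupby(
        ["participant", "condition", "nf_direction"]
    ):
        rt = g.rt_s.to_numpy(dtype=float)
        rb = g.relative_beta.to_numpy(dtype=float)
        ok = len(g) >= 5 and rt.std() > 0 and rb.std() > 0
        rows.append(
            {
                "participant": part,
                "condition": cond,
                "nf_direction": d,
                "r": float(corr(rt, rb)[0]) if ok else np.nan,
                "n_trials": len(g),
                "valid": ok,
            }
        )
    out = pd.DataFrame(rows)
    if not out.valid.all():
        bad = out[~out.valid]
        warnings.warn(
            f"{len(bad)} correlation cell(s) null (insufficient trials or "
            "zero variance)"
        )
    return out


def condition_anova(correlations: pd.DataFrame) -> tuple:
    """Repeated-measures ANOVA over the four cells, on Fisher-z r values.

    Participants missing any cell are excluded (logged).  Returns the F
    test as a StatResult plus a DataFrame of all six pairwise paired-t
    contrasts with Tukey-corrected p-values (studentized-range reference
    distribution, k = 4, df = n - 1).
    """
    import pingouin as pg

    df = correlations.copy()
    df["cell"] = df.condition + "-" + df.nf_direction
    wide = df.pivot(index="participant", columns="cell", values="r")
    cells = [f"{c}-{d}" for c, d in CELLS]
    complete = wide.dropna(subset=cells)
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        warnings.warn(f"participants excluded for missing cells: {dropped}")
    n = len(complete)
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 complete participants")
    z = np.arctanh(complete[cells].to_numpy())
    long = pd.DataFrame(
        {
            "participant": np.repeat(complete.index.to_numpy(), len(cells)),
            "cell": np.tile(cells, n),
            "z": z.ravel(),
        }
    )
    # degenerate layouts (no between-cell variation, or every participant
    # flat across cells) make the RM F-ratio 0/0; report F=0 instead
    if np.allclose(z.std(axis=0), 0) or np.allclose(
        z, z.mean(axis=1, keepdims=True)
    ):
        anova_res = StatResult(statistic=0.0, statistic_name="F", p_value=1.0,
                               label="condition", df=(3, 3 * (n - 1)),
                               degenerate=True, n=n)
    else:
        aov = pg.rm_anova(data=long, dv="z", within="cell",
                          subject="participant", detailed=False)
        anova_res = StatResult(
            statistic=float(aov.loc[0, "F"]), statistic_name="F",
            p_value=float(aov.loc[0, "p_unc"]), label="condition",
            df=(int(aov.loc[0, "ddof1"]), int(aov.loc[0, "ddof2"])), n=n,
        )
    rows = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            a, b = cells[i], cells[j]
            t, _ = sstats.ttest_rel(z[:, i], z[:, j])
            if np.isnan(t):
                p_adj = np.nan
            else:
                p_adj = float(
                    sstats.studentized_range.sf(abs(t) * np.sqrt(2), len(cells),
                                                n - 1)
                )
            rows.append({"contrast": f"{a} vs {b}", "t": float(t),
                         "df": n - 1, "p_tukey": p_adj})
    return anova_res, pd.DataFrame(rows)


def session_trial_table(
    epochs: Sequence[Epoch], r_beta: tuple
) -> pd.DataFrame:
    """Per-trial table of relative beta + behavior from pre-cue epochs."""
    rows = []
    for ep in epochs:
        rb = relative_beta(ep, r_beta)
        rows.append(
            {
                "participant": ep.participant,
                "trial_index": ep.trial_index,
                "trial_type": ep.trial_type,
                "condition": ep.condition,
                "nf_direction": ep.nf_direction,
                "rt_s": ep.rt_s,
                "relative_beta": rb.value_db,
            }
        )
    return pd.DataFrame(rows)
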