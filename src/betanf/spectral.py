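"""PSD and beta-power primitives shared by calibration, the real-time
engine, and offline analysis.

The real-time convention is fixed once here and reused everywhere: power
spectral density on 500 ms windows (250 samples at 500 Hz), linear detrend,
symmetric Hamming taper, squared magnitude of the one-sided DFT, no
zero-padding and no density scaling.  That yields a 2 Hz frequency grid;
every threshold in the protocol lives on this internally consistent scale,
so absolute calibration is irrelevant but cross-stage comparability is
mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import EegRecording

__all__ = [
    "PsdEstimate",
    "BetaTimeseries",
    "psd_window",
    "band_power",
    "sliding_beta_power",
    "clean_outliers",
    "scaled_mad_flags",
    "WINDOW_S",
    "STEP_S",
]

#: real-time analysis window (s): PSD on the last 500 ms of the stream
WINDOW_S = 0.5
#: real-time update step (s): one beta value every 250 ms
STEP_S = 0.25
#: scale factor making the MAD a consistent estimator of sigma
MAD_SCALE = 1.4826


@dataclass
class PsdEstimate:
    """One-sided squared-magnitude spectrum of a single analysis window."""

    freqs_hz: np.ndarray
    power: np.ndarray
    window_len_samples: int
    rate_hz: float

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)


@dataclass
class BetaTimeseries:
    """Band power on the 250 ms update grid.

    ``times_s[i]`` is the *end* of the 500 ms window that produced
    ``values[i]`` (the real-time loop only ever sees trailing windows).
    Values are non-negative raw band power; they may go negative after
    baselining, which produces a plain array, not this type.
    """

    times_s: np.ndarray
    values: np.ndarray
    band_hz: tuple
    alignment: str = "recording"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times_s and values must have equal length")

    def __len__(self) -> int:
        return self.values.shape[0]


def psd_window(samples: np.ndarray, rate_hz: float = 500.0) -> PsdEstimate:
    """PSD of one real-time analysis window.

    Linear detrend, symmetric Hamming taper, FFT, squared magnitude on the
    one-sided grid.  The window length is whatever is passed in (the
    protocol uses 250 samples = 500 ms at 500 Hz); no zero padding, so the
    bin spacing is ``rate_hz / len(samples)``.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("psd_window expects a 1-D window of >= 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("psd_window received non-finite samples")
    n = x.size
    x = sps.detrend(x, type="linear")
    w = sps.windows.hamming(n, sym=True)
    spec = np.fft.rfft(x * w)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    return PsdEstimate(freqs_hz=freqs, power=power,
                       window_len_samples=n, rate_hz=rate_hz)


def band_power(psd: PsdEstimate, band_hz: tuple) -> float:
    """Mean PSD over the bins with ``lo <= f <= hi`` (both ends inclusive)."""
    lo, hi = band_hz
    if lo > hi:
        raise ValueError(f"band lower edge {lo} above upper edge {hi}")
    mask = (psd.freqs_hz >= lo - 1e-9) & (psd.freqs_hz <= hi + 1e-9)
    if not mask.any():
        raise ValueError(
            f"band [{lo}, {hi}] Hz contains no bins of the "
            f"{psd.freqs_hz[1] - psd.freqs_hz[0]:g} Hz grid"
        )
    return float(psd.power[mask].mean())


def sliding_beta_power(
    recording: EegRecording,
    band_hz: tuple,
    step_s: float = STEP_S,
    window_s: float = WINDOW_S,
) -> BetaTimeseries:
    """Band power every ``step_s`` on the trailing ``window_s`` of stream.

    Emulates the online computation: the first value is available once a
    full window has arrived (t = ``window_s``), then one value per step up
    to the end of the recording.
    """
    fs = recording.rate_hz
    nwin = int(round(window_s * fs))
    nstep = int(round(step_s * fs))
    if recording.n_samples < nwin:
        raise ValueError(
            f"recording of {recording.duration_s:g} s shorter than the "
            f"{window_s:g} s analysis window"
        )
    ends = np.arange(nwin, recording.n_samples + 1, nstep)
    values = np.empty(ends.size)
    for i, e in enumerate(ends):
        psd = psd_window(recording.data[e - nwin:e], fs)
        values[i] = band_power(psd, band_hz)
    times = recording.start_time_s + ends / fs
    return BetaTimeseries(times_s=times, values=values, band_hz=band_hz)


def scaled_mad_flags(values: np.ndarray) -> np.ndarray:
    """Boolean mask of outliers under the 3-scaled-MAD rule.

    An entry is an outlier when |x - median| > 3 * 1.4826 * MAD with
    MAD = median(|x - median|).  When the MAD is zero (e.g. a constant
    majority) the strict inequality flags exactly the entries that differ
    from the median, leaving constant series untouched.
    """
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    dev = np.abs(x - med)
    mad = np.median(dev)
    return dev > 3.0 * MAD_SCALE * mad


def clean_outliers(series: BetaTimeseries) -> BetaTimeseries:
    """Replace scaled-MAD outliers by linear interpolation of neighbours.

    Interior outliers are linearly interpolated between the nearest
    non-flagged entries; outliers at the edges take the value of the
    nearest non-flagged entry.  Raises if everything is flagged (degenerate
    series with no anchor points) or the series is shorter than 3.
    """
    if len(series) < 3:
        raise ValueError("clean_outliers needs a series of length >= 3")
    flags = scaled_mad_flags(series.values)
    if flags.all():
        raise ValueError("all entries flagged as outliers; series degenerate")
    if not flags.any():
        return series
    keep = ~flags
    idx = np.arange(len(series))
    # np.interp clamps to the end values, which is exactly the edge rule
    cleaned = series.values.copy()
    cleaned[flags] = np.interp(idx[flags], idx[keep], series.values[keep])
    return BetaTimeseries(
        times_s=series.times_s.copy(),
        values=cleaned,
        band_hz=series.band_hz,
        alignment=series.alignment,
    )
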