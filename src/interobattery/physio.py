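"""Resting-state cardiorespiratory feature extraction.

Turns a raw ECG trace and a respiration-belt trace into the four physiological
predictors used by the regression models:

* mean heart rate (beats/min),
* HF (0.15-0.4 Hz) log spectral power of the RR tachogram (log ms^2),
* LF/HF power ratio,
* breath frequency (breaths/min).

The chain is the classic one: QRS detection with an adaptive dual-threshold
Pan-Tompkins detector, tachogram construction, cubic-spline resampling of the
RR series at 4 Hz, detrending, and a Welch periodogram integrated over the
standard LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal, sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "SampledSignal",
    "RPeakSeries",
    "Tachogram",
    "HrvFeatures",
    "BreathFeatures",
    "detect_r_peaks",
    "build_tachogram",
    "hrv_frequency_features",
    "breath_frequency",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass
class SampledSignal:
    """A uniformly sampled 1-D trace (amplitude units are arbitrary)."""

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class RPeakSeries:
    """R-peak event times in seconds, strictly increasing."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("R-peak times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise ValueError("R-peak times must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class Tachogram:
    """Successive RR intervals (s) and the time of each interval's end (s)."""

    rr_intervals: np.ndarray
    rr_times: np.ndarray

    def __post_init__(self) -> None:
        self.rr_intervals = np.asarray(self.rr_intervals, dtype=float)
        self.rr_times = np.asarray(self.rr_times, dtype=float)
        if self.rr_intervals.shape != self.rr_times.shape:
            raise ValueError("rr_intervals and rr_times must have equal length")
        if np.any(self.rr_intervals <= 0):
            raise ValueError("RR intervals must be positive")

    @property
    def span(self) -> float:
        """Time covered by the tachogram, in seconds."""
        return float(self.rr_times[-1] - self.rr_times[0] + self.rr_intervals[0])


@dataclass(frozen=True)
class HrvFeatures:
    mean_hr: float  # beats/min
    hf_log_power: float  # log(ms^2), natural log of integrated HF band power
    lf_hf_ratio: float
    lf_power: float  # ms^2, kept for diagnostics
    hf_power: float  # ms^2


@dataclass(frozen=True)
class BreathFeatures:
    breath_frequency: float  # breaths/min
    cycle_onsets: np.ndarray  # inhalation onset times, s


# --------------------------------------------------------------------------- #
# QRS detection
# --------------------------------------------------------------------------- #

def detect_r_peaks(ecg: SampledSignal) -> RPeakSeries:
    """Detect R-peaks with a Pan-Tompkins style adaptive detector.

    Band-pass (5-15 Hz) -> derivative -> squaring -> 150 ms moving-window
    integration -> adaptive dual threshold with a 200 ms refractory period and
    searchback.  Each detection is then refined to the raw-signal maximum
    within +/-50 ms so the returned times sit on the R wave itself.
    """
    fs = ecg.sampling_rate
    x = ecg.samples
    if ecg.duration < 2.0:
        raise ValueError("need at least 2 s of ECG signal")
    if np.ptp(x) == 0:
        warnings.warn("flat ECG signal: no R-peaks detected", stacklevel=2)
        return RPeakSeries(np.empty(0))

    sos = signal.butter(2, [5.0, 15.0], btype="band", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    sq = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    cand, _ = signal.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        warnings.warn("no QRS candidates found", stacklevel=2)
        return RPeakSeries(np.empty(0))

    # adaptive dual threshold (running signal/noise peak estimates)
    init = mwi[: int(2 * fs)]
    spki = 0.25 * init.max()
    npki = 0.5 * np.mean(init)
    qrs: list[int] = []
    rr_hist: list[float] = []
    for i, c in enumerate(cand):
        thr1 = npki + 0.25 * (spki - npki)
        if mwi[c] > thr1:
            qrs.append(c)
            spki = 0.125 * mwi[c] + 0.875 * spki
            if len(qrs) >= 2:
                rr_hist.append((qrs[-1] - qrs[-2]) / fs)
                rr_hist = rr_hist[-8:]
        else:
            npki = 0.125 * mwi[c] + 0.875 * npki
            # searchback: long gap since the last accepted QRS
            if qrs and rr_hist:
                rr_avg = float(np.mean(rr_hist))
                if (c - qrs[-1]) / fs > 1.66 * rr_avg and mwi[c] > 0.5 * thr1:
                    qrs.append(c)
                    spki = 0.25 * mwi[c] + 0.75 * spki
                    rr_hist.append((qrs[-1] - qrs[-2]) / fs)
                    rr_hist = rr_hist[-8:]

    if not qrs:
        warnings.warn("no QRS passed the adaptive threshold", stacklevel=2)
        return RPeakSeries(np.empty(0))

    # refine each detection to the raw-signal maximum within +/-50 ms
    half = int(round(0.050 * fs))
    refined = []
    for c in qrs:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    # enforce refractory after refinement
    keep = [refined[0]]
    for r in refined[1:]:
        if r - keep[-1] >= refractory:
            keep.append(r)
    times = ecg.start_time + np.asarray(keep) / fs
    return RPeakSeries(times)


# --------------------------------------------------------------------------- #
# Tachogram
# --------------------------------------------------------------------------- #

def build_tachogram(
    peaks: RPeakSeries,
    *,
    artifact_correction: bool = False,
    bounds: tuple[float, float] = (0.3, 2.0),
    median_window: int = 5,
    max_rel_dev: float = 0.30,
) -> Tachogram:
    """RR intervals between consecutive R-peaks.

    With ``artifact_correction`` enabled, intervals outside *bounds* or
    deviating more than ``max_rel_dev`` from the local running median are
    replaced by cubic interpolation over the surrounding good intervals.
    Correction is off by default.
    """
    t = peaks.times
    if len(peaks) < 2:
        raise ValueError("need at least 2 R-peaks to build a tachogram")
    rr = np.diff(t)
    rr_times = t[1:]
    if artifact_correction:
        med = _running_median(rr, median_window)
        bad = (rr < bounds[0]) | (rr > bounds[1]) | (np.abs(rr - med) > max_rel_dev * med)
        if bad.any() and (~bad).sum() >= 4:
            idx = np.arange(rr.size)
            f = interpolate.interp1d(
                idx[~bad], rr[~bad], kind="cubic", fill_value="extrapolate"
            )
            rr = rr.copy()
            rr[bad] = f(idx[bad])
    return Tachogram(rr, rr_times)


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


# --------------------------------------------------------------------------- #
# Frequency-domain HRV
# --------------------------------------------------------------------------- #

def _smoothness_priors_detrend(z: np.ndarray, lam: float) -> np.ndarray:
    """Remove the low-frequency trend with a second-difference smoothness prior."""
    n = z.size
    if n < 3:
        return z - z.mean()
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    a = sparse.identity(n, format="csc") + (lam**2) * (d2.T @ d2)
    trend = spsolve(a.tocsc(), z)
    return z - trend


def hrv_frequency_features(
    tach: Tachogram,
    *,
    interp_rate: float = 4.0,
    detrend: str = "smoothness_priors",
    detrend_lambda: float = 500.0,
    segment_seconds: float = 120.0,
) -> HrvFeatures:
    """Welch-periodogram HRV features from a tachogram.

    RR intervals (in ms) are cubic-spline interpolated onto a uniform
    ``interp_rate`` grid, detrended (smoothness priors by default, ``"linear"``
    as alternative), and a Welch PSD (Hann window, 50% overlap, segment length
    ``segment_seconds`` or the full record if shorter) is integrated over the
    LF and HF bands.  ``hf_log_power`` is the natural log of the integrated
    HF power in ms^2.
    """
    span = tach.rr_times[-1] - tach.rr_times[0]
    if span < 60.0:
        raise ValueError("tachogram must span at least 60 s for spectral analysis")
    rr_s = tach.rr_intervals
    mean_hr = 60.0 / float(np.mean(rr_s))

    rr_ms = rr_s * 1000.0
    cs = interpolate.CubicSpline(tach.rr_times, rr_ms)
    grid = np.arange(tach.rr_times[0], tach.rr_times[-1], 1.0 / interp_rate)
    z = cs(grid)

    if detrend == "smoothness_priors":
        z = _smoothness_priors_detrend(z, detrend_lambda)
    elif detrend == "linear":
        z = signal.detrend(z, type="linear")
    else:
        raise ValueError(f"unknown detrend method {detrend!r}")

    nperseg = min(z.size, int(segment_seconds * interp_rate))
    freqs, psd = signal.welch(
        z,
        fs=interp_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
    )
    lf = _band_power(freqs, psd, LF_BAND)
    hf = _band_power(freqs, psd, HF_BAND)
    if hf <= 1e-12:  # ms^2; constant RR leaves only numerical dust
        raise ValueError("degenerate spectrum: HF band power is zero")
    return HrvFeatures(
        mean_hr=mean_hr,
        hf_log_power=float(np.log(hf)),
        lf_hf_ratio=float(lf / hf),
        lf_power=float(lf),
        hf_power=float(hf),
    )


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


# --------------------------------------------------------------------------- #
# Respiration
# --------------------------------------------------------------------------- #

def breath_frequency(
    resp: SampledSignal,
    *,
    lowpass_hz: float = 1.0,
    min_prominence_sd: float = 0.25,
) -> BreathFeatures:
    """Breaths per minute from a respiration-belt trace.

    The trace is low-pass smoothed at ``lowpass_hz``; inspiratory peaks are
    gated by prominence (relative to the trace SD, so the result is invariant
    to amplitude scaling) and each cycle onset is the preceding positive-going
    crossing of the trace mean.  Breath frequency is the number of complete
    onset-to-onset cycles divided by the time they span, in minutes.
    """
    if resp.duration < 30.0:
        raise ValueError("need at least 30 s of respiration signal")
    x = resp.samples
    fs = resp.sampling_rate
    sd = float(np.std(x))
    if sd == 0:
        warnings.warn("flat respiration signal: breath frequency set to 0", stacklevel=2)
        return BreathFeatures(0.0, np.empty(0))
    if fs > 2 * lowpass_hz:
        sos = signal.butter(2, lowpass_hz, btype="low", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
    x = x - np.mean(x)
    peaks, _ = signal.find_peaks(x, prominence=min_prominence_sd * sd)

    onsets = []
    prev_peak = -np.inf
    for p in peaks:
        # last upward zero-crossing (of the mean-removed trace) before the peak
        seg = x[:p]
        below = np.flatnonzero((seg[:-1] < 0) & (seg[1:] >= 0))
        if below.size == 0:
            continue
        onset = int(below[-1]) + 1
        if onset > prev_peak:  # one onset per cycle
            onsets.append(onset)
            prev_peak = p
    onsets = np.unique(onsets)
    if onsets.size < 2:
        warnings.warn("fewer than 2 breath onsets detected", stacklevel=2)
        return BreathFeatures(0.0, resp.start_time + onsets / fs)
    span_min = (onsets[-1] - onsets[0]) / fs / 60.0
    freq = (onsets.size - 1) / span_min
    return BreathFeatures(float(freq), resp.start_time + onsets / fs)
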