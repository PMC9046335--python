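"""Beat detection, inter-beat-interval correction, and heart-rate variability.

A pulse (PPG-like) or ECG-like waveform is low-pass filtered (zero-phase,
10–20 Hz cutoff), beats are detected as threshold-crossing local maxima —
either a *global* threshold (fraction of the trace maximum) or a *local*
threshold (fraction of a running-window maximum, robust to drift) — with a
250 ms refractory period and parabolic sub-sample refinement of each peak
time.

RR intervals beyond median ± 4·MAD of the recording's own interval
distribution are flagged as artifacts (a simplified threshold proxy in the
spirit of distribution-based IBI artifact detection) and replaced by cubic
spline interpolation over beat index, yielding the NN series.

Time-domain HRV (SDNN, RMSSD, NN50, pNN50) is computed directly on the NN
intervals; frequency-domain LF/HF power integrates a Welch spectrum of the
cubic-spline NN tachogram resampled at 4 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .containers import NNSeries, PhysioTrace

__all__ = [
    "HRVMetrics",
    "lowpass",
    "detect_beats",
    "ibi_artifacts",
    "correct_artifacts",
    "build_nn_series",
    "heart_rate",
    "hrv_time",
    "hrv_freq",
    "hrv_metrics",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass
class HRVMetrics:
    hr_bpm: float
    sdnn_ms: float
    rmssd_ms: float
    nn50: int
    pnn50: float
    lf_ms2: float
    hf_ms2: float


def lowpass(trace: PhysioTrace, cutoff_hz: float = 15.0, order: int = 4) -> PhysioTrace:
    """Zero-phase Butterworth low-pass filter; cutoff must be below Nyquist."""
    nyq = trace.rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trace.rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.value)
    return PhysioTrace(t=trace.t, value=filtered, rate_hz=trace.rate_hz, units=trace.units)


def _refine_peak(t: np.ndarray, v: np.ndarray, i: int) -> float:
    """Parabolic interpolation of a peak time through three samples."""
    if i <= 0 or i >= len(v) - 1:
        return float(t[i])
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(t[i])
    delta = 0.5 * (y0 - y2) / denom
    dt = (t[i + 1] - t[i - 1]) / 2.0
    return float(t[i] + np.clip(delta, -1, 1) * dt)


def detect_beats(
    trace: PhysioTrace,
    method: Literal["global_threshold", "local_threshold"] = "global_threshold",
    threshold_frac: float = 0.5,
    refractory_s: float = 0.25,
    local_window_s: float = 2.0,
) -> np.ndarray:
    """Detect beat times as supra-threshold local maxima of the waveform.

    ``global_threshold``: peaks above ``threshold_frac`` × trace maximum.
    ``local_threshold``: above the same fraction of a centered running-window
    maximum (robust to slow drift). Peaks closer than the refractory period
    are suppressed; returned times are parabolic-refined.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    v = trace.value
    if np.ptp(v) == 0:
        import warnings

        warnings.warn("flat trace: no beats detected")
        return np.array([])
    distance = max(int(refractory_s * trace.rate_hz), 1)
    peaks, _ = signal.find_peaks(v, distance=distance)
    if method == "global_threshold":
        height = v.min() + threshold_frac * (v.max() - v.min())
        peaks = peaks[v[peaks] >= height]
    elif method == "local_threshold":
        w = max(int(local_window_s * trace.rate_hz) | 1, 3)
        from scipy.ndimage import maximum_filter1d, minimum_filter1d

        local_max = maximum_filter1d(v, size=w, mode="nearest")
        local_min = minimum_filter1d(v, size=w, mode="nearest")
        height = local_min + threshold_frac * (local_max - local_min)
        peaks = peaks[v[peaks] >= height[peaks]]
    else:
        raise ValueError(f"unknown beat-detection method {method!r}")
    return np.array([_refine_peak(trace.t, v, int(p)) for p in peaks])


def ibi_artifacts(rr_ms: np.ndarray, k: float = 4.0) -> np.ndarray:
    """Flag RR intervals beyond median ± k·MAD of the interval distribution.

    A simplified distribution-threshold proxy: missed beats (doubled
    intervals) and spurious beats (halved intervals) are far outside the
    robust band of a physiological RR distribution.
    """
    rr = np.asarray(rr_ms, float)
    if len(rr) < 5:
        raise ValueError("need at least 5 intervals for artifact detection")
    med = np.median(rr)
    mad = np.median(np.abs(rr - med))
    if mad == 0:
        return np.zeros(len(rr), bool)
    return np.abs(rr - med) > k * mad


def correct_artifacts(rr_ms: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Replace flagged intervals by cubic-spline interpolation over beat index."""
    rr = np.asarray(rr_ms, float)
    flags = np.asarray(flags, bool)
    if not flags.any():
        return rr.copy()
    good = ~flags
    if good.sum() < 4:
        raise ValueError("too few clean intervals for spline correction")
    idx = np.arange(len(rr))
    spline = CubicSpline(idx[good], rr[good])
    nn = rr.copy()
    nn[flags] = spline(idx[flags])
    return nn


def build_nn_series(beat_times: np.ndarray, k: float = 4.0) -> NNSeries:
    """Beat times → RR intervals → artifact flags → corrected NN series."""
    nn = NNSeries(beat_times=np.asarray(beat_times, float))
    flags = ibi_artifacts(nn.rr_ms, k=k)
    nn.artifact = flags
    nn.nn_ms = correct_artifacts(nn.rr_ms, flags)
    return nn


def heart_rate(nn_ms: np.ndarray, window_beats: int = 3) -> np.ndarray:
    """Moving-average heart rate (bpm): 60000 / mean of the last ``window_beats`` NN.

    Returns one value per window position (length ``n − window_beats + 1``).
    A window of 1 reduces to the instantaneous rate.
    """
    nn = np.asarray(nn_ms, float)
    if len(nn) < window_beats:
        raise ValueError(f"need at least {window_beats} intervals")
    kernel = np.ones(window_beats) / window_beats
    means = np.convolve(nn, kernel, mode="valid")
    return 60000.0 / means


def hrv_time(nn_ms: np.ndarray) -> Tuple[float, float, int, float]:
    """(SDNN, RMSSD, NN50, pNN50) of an NN interval series in ms.

    SDNN is the sample SD (ddof=1); RMSSD the root mean square of successive
    differences; NN50 the count of successive differences exceeding 50 ms;
    pNN50 that count as a percentage of the n−1 successive pairs.
    """
    nn = np.asarray(nn_ms, float)
    if len(nn) < 2:
        raise ValueError("need at least 2 intervals")
    sdnn = float(np.std(nn, ddof=1))
    d = np.diff(nn)
    rmssd = float(np.sqrt(np.mean(d**2)))
    nn50 = int(np.sum(np.abs(d) > 50.0))
    pnn50 = 100.0 * nn50 / len(d)
    return sdnn, rmssd, nn50, pnn50


def hrv_freq(
    nn_ms: np.ndarray,
    beat_times: np.ndarray,
    resample_hz: float = 4.0,
    segment_s: float = 64.0,
) -> Tuple[float, float]:
    """(LF, HF) absolute band power of the NN tachogram, in ms².

    The NN series is interpolated over beat time with a cubic spline,
    resampled at ``resample_hz``, mean-removed, and a Welch spectrum with
    50%-overlapping segments is integrated over 0.04–0.15 Hz (LF) and
    0.15–0.4 Hz (HF).
    """
    nn = np.asarray(nn_ms, float)
    bt = np.asarray(beat_times, float)
    if len(nn) != len(bt) - 1:
        raise ValueError("expected one NN interval per consecutive beat pair")
    span = bt[-1] - bt[1]
    if span < 1.0 / LF_BAND[0]:
        raise ValueError("record shorter than one LF cycle (25 s)")
    # tachogram: NN value attributed to the interval's closing beat
    spline = CubicSpline(bt[1:], nn)
    tt = np.arange(bt[1], bt[-1], 1.0 / resample_hz)
    tach = spline(tt)
    tach = tach - tach.mean()
    nperseg = min(int(segment_s * resample_hz), len(tach))
    freqs, psd = signal.welch(tach, fs=resample_hz, nperseg=nperseg,
                              noverlap=nperseg // 2, detrend="linear")
    df = freqs[1] - freqs[0]
    lf = float(np.sum(psd[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])]) * df)
    hf = float(np.sum(psd[(freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])]) * df)
    return lf, hf


def hrv_metrics(nn: NNSeries) -> HRVMetrics:
    """All HR/HRV metrics for a corrected NN series."""
    intervals = nn.intervals()
    sdnn, rmssd, nn50, pnn50 = hrv_time(intervals)
    hr = heart_rate(intervals)
    lf, hf = hrv_freq(intervals, nn.beat_times)
    return HRVMetrics(
        hr_bpm=float(np.mean(hr)),
        sdnn_ms=sdnn,
        rmssd_ms=rmssd,
        nn50=nn50,
        pnn50=pnn50,
        lf_ms2=lf,
        hf_ms2=hf,
    )
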