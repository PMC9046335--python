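"""Skin-conductance preprocessing, event-related responses, device agreement.

The raw trace (µS, typically 150 Hz) is anti-alias filtered and decimated
to 10 Hz, then smoothed with a Gaussian kernel whose width adapts to the
local noise level (wider where the residual variance is higher) — a simple
stand-in for the adaptive smoothing step of interactive SC packages.

The event-related response is a window statistic: the maximum of the
smoothed signal in a post-event response window (default 1–5 s) minus the
mean over a pre-event baseline window (default 1 s). No tonic/phasic
deconvolution is attempted.

Agreement between two devices recording the same construct is summarised
by Pearson and Kendall rank correlations over paired trial- or
participant-level aggregates; both are invariant to affine rescaling of
either signal, which is what matters when one device's output spans a
smaller range.
"""

from __future__ import annotations

from typing import Literal, Tuple

import numpy as np
from scipy import signal, stats
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .containers import PhysioTrace

__all__ = ["preprocess_sc", "event_response", "device_agreement"]


def _adaptive_gaussian_smooth(
    v: np.ndarray, sigma_min: float = 2.0, sigma_max: float = 8.0,
    noise_ref_us: float = 0.05,
) -> np.ndarray:
    """Gaussian smoothing with a per-sample kernel SD driven by local noise.

    Local noise SD is estimated from second differences, which cancel both
    the tonic trend and the (locally near-linear) SCR slopes at 10 Hz; for
    white noise the second-difference variance is six times the noise
    variance. The kernel SD scales linearly from ``sigma_min`` samples on
    clean stretches to ``sigma_max`` where the local noise SD reaches
    ``noise_ref_us`` (µS) — an absolute reference, so a noise-free SCR is
    not smoothed away.
    """
    if len(v) < 5:
        return v.copy()
    d2 = np.diff(v, n=2)
    d2 = np.concatenate([d2[:1], d2, d2[-1:]])
    local_sd = np.sqrt(np.maximum(uniform_filter1d(d2**2, size=21, mode="nearest") / 6.0, 0.0))
    frac = np.clip(local_sd / noise_ref_us, 0.0, 1.0)
    sigmas = sigma_min + (sigma_max - sigma_min) * frac
    # a small bank of fixed-width smooths, blended per sample
    grid = np.linspace(sigma_min, sigma_max, 4)
    bank = np.stack([gaussian_filter1d(v, s) for s in grid])
    idx = np.clip(np.searchsorted(grid, sigmas) - 1, 0, len(grid) - 2)
    w = (sigmas - grid[idx]) / (grid[idx + 1] - grid[idx])
    cols = np.arange(len(v))
    return bank[idx, cols] * (1 - w) + bank[idx + 1, cols] * w


def preprocess_sc(trace: PhysioTrace, target_hz: float = 10.0) -> PhysioTrace:
    """Anti-alias filter, decimate to ``target_hz``, adaptively smooth.

    The input rate must be an (approximate) integer multiple of the target
    and at least the target. Decimation uses zero-phase FIR anti-alias
    filtering, cascaded when the factor is large.
    """
    if trace.rate_hz < target_hz:
        raise ValueError(f"trace rate {trace.rate_hz} Hz below target {target_hz} Hz")
    q = int(round(trace.rate_hz / target_hz))
    # remove the (large) tonic mean before FIR filtering to avoid zero-padding
    # edge transients, restore after
    mu = float(np.mean(trace.value))
    v = trace.value - mu
    if q > 1:
        # cascade: factors > 13 are numerically poor in one step
        factors = []
        rem = q
        for f in (5, 3, 2):
            while rem % f == 0 and rem > 1:
                factors.append(f)
                rem //= f
        if rem > 1:
            factors.append(rem)
        for f in factors:
            v = signal.decimate(v, f, ftype="fir", zero_phase=True)
    rate = trace.rate_hz / q
    t = trace.t[0] + np.arange(len(v)) / rate
    smoothed = _adaptive_gaussian_smooth(v) + mu
    return PhysioTrace(t=t, value=smoothed, rate_hz=rate, units=trace.units)


def event_response(
    trace: PhysioTrace,
    event_time: float,
    baseline_window_s: Tuple[float, float] = (1.0, 0.0),
    response_window_s: Tuple[float, float] = (1.0, 5.0),
    statistic: Literal["peak", "mean"] = "peak",
) -> float:
    """Event-related SC response amplitude (µS).

    ``baseline_window_s = (pre, post)`` bounds the baseline as
    [event − pre, event − post); ``response_window_s = (start, end)`` the
    response as [event + start, event + end]. The amplitude is the response
    maximum (or mean) minus the baseline mean. Windows must lie within the
    trace.
    """
    t = trace.t
    b0, b1 = event_time - baseline_window_s[0], event_time - baseline_window_s[1]
    r0, r1 = event_time + response_window_s[0], event_time + response_window_s[1]
    if b0 < t[0] or r1 > t[-1]:
        raise ValueError("event windows fall outside the trace")
    base = trace.value[(t >= b0) & (t < b1)]
    resp = trace.value[(t >= r0) & (t <= r1)]
    if len(base) == 0 or len(resp) == 0:
        raise ValueError("empty baseline or response window")
    stat = np.max(resp) if statistic == "peak" else np.mean(resp)
    return float(stat - np.mean(base))


def device_agreement(
    series_a: np.ndarray,
    series_b: np.ndarray,
    level: Literal["trial", "participant"] = "trial",
) -> dict:
    """Pearson and Kendall correlations between paired device aggregates.

    ``level`` records the aggregation the caller used (per-trial means or
    per-participant summaries); the statistics are the same either way.
    Kendall's tau is the small-sample-appropriate rank statistic.
    """
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired observations")
    pear = stats.pearsonr(a, b)
    kend = stats.kendalltau(a, b)
    return dict(
        level=level,
        pearson_r=float(pear.statistic),
        pearson_p=float(pear.pvalue),
        kendall_tau=float(kend.statistic),
        kendall_p=float(kend.pvalue),
        n=len(a),
    )
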