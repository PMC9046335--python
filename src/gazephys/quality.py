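"""Eye-tracking data-quality metrics.

Implements the standard per-trial quality battery for a remote tracker:

* sampling-rate variability — mean/SD and median/MAD of the inter-sample
  time, plus the proportion of intervals longer than two nominal periods;
* data loss — proportion of device-invalid and off-screen samples per trial;
* accuracy — per-sample horizontal (A_H), vertical (A_V) and global
  Euclidean (A_G) angular error to the known target, averaged per trial
  after trimming the first/last 250 ms and median±4·MAD outlier removal;
* precision — RMS of sample-to-sample angular steps (RMS-S2S) within
  fixations longer than 80 ms;
* drift over trials — per-participant OLS trends on orthogonal linear and
  quadratic trial-index polynomials with a block indicator.

A_G is computed per sample as the Euclidean norm of the axis errors, so
``A_G² = A_H² + A_V²`` holds exactly before any averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import GazeRecording
from .events import EventSegmentation
from .geometry import ScreenGeometry

__all__ = [
    "SamplingStats",
    "TrendModel",
    "inter_sample_stats",
    "data_loss",
    "trim_trial",
    "sample_accuracy",
    "remove_outliers_mad",
    "trial_precision",
    "trend_over_trials",
    "quality_report",
]


@dataclass
class SamplingStats:
    mean_ms: float
    sd_ms: float
    median_ms: float
    mad_ms: float
    prop_long: float  # proportion of intervals > 2 nominal periods
    n_intervals: int


def inter_sample_stats(rec: GazeRecording) -> SamplingStats:
    """Mean/SD and median/MAD of the inter-sample time, in milliseconds."""
    t = rec.t
    if len(t) < 2:
        raise ValueError("need at least 2 samples for inter-sample statistics")
    dt = np.diff(t) * 1000.0
    med = float(np.median(dt))
    long_cutoff = 2.0 * 1000.0 / rec.nominal_rate_hz
    return SamplingStats(
        mean_ms=float(np.mean(dt)),
        sd_ms=float(np.std(dt, ddof=1)) if len(dt) > 1 else 0.0,
        median_ms=med,
        mad_ms=float(np.median(np.abs(dt - med))),
        prop_long=float(np.mean(dt > long_cutoff)),
        n_intervals=len(dt),
    )


def data_loss(
    rec: GazeRecording,
    geometry: Optional[ScreenGeometry] = None,
    onset: Optional[float] = None,
    offset: Optional[float] = None,
) -> dict:
    """Proportion of lost samples (device-invalid or off-screen) in a window.

    Off-screen uses half-open bounds [0, width_px) × [0, height_px).
    Returns the two components separately plus their union. An empty window
    yields NaN proportions with ``n == 0`` (flagged, not zero).
    """
    geo = geometry if geometry is not None else rec.geometry
    t = rec.t
    mask = np.ones(len(t), bool)
    if onset is not None:
        mask &= t >= onset
    if offset is not None:
        mask &= t < offset
    n = int(mask.sum())
    if n == 0:
        return dict(loss=np.nan, invalid=np.nan, offscreen=np.nan, n=0)
    valid = rec.valid[mask]
    xy = rec.xy[mask]
    invalid = ~valid
    with np.errstate(invalid="ignore"):
        offscreen = valid & ~(
            (xy[:, 0] >= 0) & (xy[:, 0] < geo.width_px) & (xy[:, 1] >= 0) & (xy[:, 1] < geo.height_px)
        )
    lost = invalid | offscreen
    return dict(
        loss=float(lost.mean()),
        invalid=float(invalid.mean()),
        offscreen=float(offscreen.mean()),
        n=n,
    )


def trim_trial(
    samples: pd.DataFrame, onset: float, offset: float, trim_ms: float = 250.0
) -> pd.DataFrame:
    """Retain samples with t in [onset + trim, offset − trim).

    Trials shorter than twice the trim window come back empty (the caller
    should flag them); the operation is idempotent on its own output window.
    """
    trim = trim_ms / 1000.0
    t = samples["t"]
    return samples[(t >= onset + trim) & (t < offset - trim)]


def sample_accuracy(
    samples: pd.DataFrame, target_px: Tuple[float, float], geometry: ScreenGeometry
) -> pd.DataFrame:
    """Per-sample angular errors to the target: columns a_h, a_v, a_g (deg).

    Invalid samples are skipped. a_g is the Euclidean norm of (a_h, a_v).
    """
    s = samples[samples["valid"].astype(bool)]
    fx = geometry.deg_per_px("horizontal")
    fy = geometry.deg_per_px("vertical")
    a_h = np.abs(s["x_px"].to_numpy(float) - target_px[0]) * fx
    a_v = np.abs(s["y_px"].to_numpy(float) - target_px[1]) * fy
    return pd.DataFrame({"t": s["t"].to_numpy(float), "a_h": a_h, "a_v": a_v,
                         "a_g": np.hypot(a_h, a_v)})


def remove_outliers_mad(values: np.ndarray, k: float = 4.0) -> np.ndarray:
    """Drop values farther than ``k`` raw MADs from the median.

    If the MAD is zero (e.g. more than half the values identical), nothing
    is dropped — the robust spread carries no information there.
    """
    v = np.asarray(values, float)
    if len(v) == 0:
        return v
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return v
    return v[np.abs(v - med) <= k * mad]


def trial_precision(
    fixation_samples: Sequence[pd.DataFrame], geometry: ScreenGeometry
) -> dict:
    """RMS-S2S precision over a trial's qualifying fixations (deg).

    ``fixation_samples`` holds one DataFrame (columns t, x_px, y_px, valid)
    per fixation with duration > 80 ms inside the trial. P_H/P_V are the RMS
    of successive axis steps; P_G the RMS of successive Euclidean step
    lengths, so P_G ≥ max(P_H, P_V). Successive pairs spanning an invalid
    sample are excluded. Returns NaNs when no fixation qualifies.
    """
    fx = geometry.deg_per_px("horizontal")
    fy = geometry.deg_per_px("vertical")
    per_fix = []
    for f in fixation_samples:
        valid = f["valid"].to_numpy(bool)
        x = f["x_px"].to_numpy(float) * fx
        y = f["y_px"].to_numpy(float) * fy
        ok = valid[1:] & valid[:-1]
        if ok.sum() < 1:
            continue
        dx = np.diff(x)[ok]
        dy = np.diff(y)[ok]
        p_h = np.sqrt(np.mean(dx**2))
        p_v = np.sqrt(np.mean(dy**2))
        p_g = np.sqrt(np.mean(dx**2 + dy**2))
        per_fix.append((p_h, p_v, p_g))
    if not per_fix:
        return dict(p_h=np.nan, p_v=np.nan, p_g=np.nan, n_fixations=0)
    arr = np.array(per_fix)
    return dict(
        p_h=float(arr[:, 0].mean()),
        p_v=float(arr[:, 1].mean()),
        p_g=float(arr[:, 2].mean()),
        n_fixations=len(per_fix),
    )


@dataclass
class TrendModel:
    """Orthogonal-polynomial trend fit of a per-trial metric.

    ``coef`` maps predictor names (linear, quadratic, block, const) to OLS
    estimates on the orthonormal trial-index basis; ``se`` to their standard
    errors. ``linear_slope_per_trial`` re-expresses the linear term as a raw
    change per trial, comparable to values like "0.04° per trial".
    """

    coef: dict
    se: dict
    linear_slope_per_trial: float
    r_squared: float
    n: int


def orthogonal_trial_polynomials(n: int) -> np.ndarray:
    """Centered, orthonormal linear and quadratic polynomials of trial index."""
    idx = np.arange(n, dtype=float)
    lin = idx - idx.mean()
    quad = lin**2 - (lin**2).mean()
    quad -= (quad @ lin) / (lin @ lin) * lin  # orthogonalize against linear
    lin /= np.linalg.norm(lin)
    norm = np.linalg.norm(quad)
    if norm > 0:
        quad /= norm
    return np.column_stack([lin, quad])


def trend_over_trials(
    metric: np.ndarray, blocks: Optional[np.ndarray] = None
) -> TrendModel:
    """OLS fit metric ~ orthogonal(linear + quadratic trial index) + block."""
    y = np.asarray(metric, float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 trials for a trend fit")
    poly = orthogonal_trial_polynomials(n)
    names = ["linear", "quadratic"]
    X = poly
    if blocks is not None:
        b = np.asarray(blocks, float)
        b = b - b.mean()
        X = np.column_stack([X, b])
        names.append("block")
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient trend design (constant block or too few trials)")
    fit = sm.OLS(y, X).fit()
    names = ["const"] + names
    coef = dict(zip(names, fit.params))
    se = dict(zip(names, fit.bse))
    # orthonormal linear basis has slope 1/||lin|| per trial step
    idx = np.arange(n, dtype=float)
    lin_raw = idx - idx.mean()
    slope_per_trial = coef["linear"] / np.linalg.norm(lin_raw)
    return TrendModel(
        coef=coef, se=se, linear_slope_per_trial=float(slope_per_trial),
        r_squared=float(fit.rsquared), n=n,
    )


def quality_report(
    rec: GazeRecording,
    trials: pd.DataFrame,
    segmentation: EventSegmentation,
    geometry: Optional[ScreenGeometry] = None,
    trim_ms: float = 250.0,
    outlier_k: Optional[float] = 4.0,
    min_fixation_ms: float = 80.0,
) -> pd.DataFrame:
    """Per-trial quality table: accuracy (A_H/A_V/A_G), precision, loss.

    For each trial the samples are trimmed by ``trim_ms`` at both ends,
    per-sample accuracies computed to the trial's target, outliers removed
    per metric at ``outlier_k`` MADs (pass ``None`` to disable, mirroring
    robustness checks with outliers retained), and the trial means reported.
    Precision uses fixations longer than ``min_fixation_ms`` whose span lies
    within the trimmed window.
    """
    geo = geometry if geometry is not None else rec.geometry
    fixes = segmentation.fixations
    rows = []
    for _, tr in trials.iterrows():
        window = trim_trial(rec.samples, tr["onset"], tr["offset"], trim_ms)
        loss = data_loss(rec, geo, tr["onset"], tr["offset"])
        row = dict(
            trial_id=tr["trial_id"],
            n_samples=len(window),
            loss=loss["loss"],
            loss_invalid=loss["invalid"],
            loss_offscreen=loss["offscreen"],
        )
        if len(window) == 0:
            row.update(a_h=np.nan, a_v=np.nan, a_g=np.nan,
                       p_h=np.nan, p_v=np.nan, p_g=np.nan, flagged_short=True)
            rows.append(row)
            continue
        acc = sample_accuracy(window, (tr["target_x_px"], tr["target_y_px"]), geo)
        for col in ("a_h", "a_v", "a_g"):
            vals = acc[col].to_numpy()
            if outlier_k is not None:
                vals = remove_outliers_mad(vals, outlier_k)
            row[col] = float(np.mean(vals)) if len(vals) else np.nan
        t0, t1 = window["t"].iloc[0], window["t"].iloc[-1]
        qual = fixes[
            (fixes["duration_ms"] > min_fixation_ms)
            & (fixes["onset_time"] >= t0)
            & (fixes["offset_time"] <= t1)
        ]
        fix_frames = [
            rec.samples.iloc[int(f.onset_idx) : int(f.offset_idx) + 1]
            for f in qual.itertuples()
        ]
        row.update(trial_precision(fix_frames, geo))
        row["flagged_short"] = False
        rows.append(row)
    return pd.DataFrame(rows)
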