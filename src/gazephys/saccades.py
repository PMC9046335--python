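"""Per-saccade metrics and the saccadic main sequence.

Metrics follow the conventions of eye-movement validation work:

amplitude
    chord length (deg) between the saccade's onset and offset samples —
    not the travelled path length.
gain
    observed amplitude divided by the expected amplitude (angular distance
    between the two target centers); < 1 hypometric, > 1 hypermetric.
curvature
    median over interior samples of the unsigned angle (deg) at the onset
    point between the onset→offset chord and the onset→sample vector; zero
    for a collinear path and invariant to rotation/translation.
starting / landing error
    angular distance between the onset (offset) sample and the starting
    (landing) target center.
latency
    saccade onset time minus target onset; anticipatory saccades yield
    negative latencies, which are reported, not clamped.
velocity
    per-sample step length over Δt; mean and peak per saccade.

The main sequence is the near-linear relation of amplitude to duration and
to peak velocity for small-to-medium saccades; it is summarised here by
per-set least-squares fits and correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GazeRecording
from .events import EventSegmentation
from .geometry import ScreenGeometry, distance_deg

__all__ = ["SaccadeMetrics", "saccade_metrics", "main_sequence", "match_saccades_to_trials"]


@dataclass
class SaccadeMetrics:
    amplitude_deg: float
    duration_ms: float
    gain: float
    curvature_deg: float  # NaN when < 3 samples
    latency_ms: float
    mean_velocity_deg_s: float
    peak_velocity_deg_s: float
    starting_error_deg: float
    landing_error_deg: float


def _chord_angles_deg(
    pts_deg: np.ndarray,
) -> np.ndarray:
    """Unsigned angle at the onset point between chord and each interior sample."""
    chord = pts_deg[-1] - pts_deg[0]
    angles = []
    for p in pts_deg[1:-1]:
        v = p - pts_deg[0]
        nv, nc = np.linalg.norm(v), np.linalg.norm(chord)
        if nv == 0 or nc == 0:
            continue
        cosang = np.clip(np.dot(v, chord) / (nv * nc), -1.0, 1.0)
        angles.append(math.degrees(math.acos(cosang)))
    return np.asarray(angles)


def saccade_metrics(
    samples: pd.DataFrame,
    start_target_px: Tuple[float, float],
    end_target_px: Tuple[float, float],
    target_onset: float,
    geometry: ScreenGeometry,
) -> SaccadeMetrics:
    """Compute all per-saccade metrics from the saccade's gaze samples.

    ``samples`` must contain columns t, x_px, y_px, ordered in time, with
    at least two rows. Raises on zero expected amplitude (gain undefined);
    curvature is NaN (flagged) with fewer than three samples.
    """
    if len(samples) < 2:
        raise ValueError("a saccade needs at least 2 samples")
    t = samples["t"].to_numpy(float)
    xy = samples[["x_px", "y_px"]].to_numpy(float)
    fx = geometry.deg_per_px("horizontal")
    fy = geometry.deg_per_px("vertical")
    pts_deg = np.column_stack([xy[:, 0] * fx, xy[:, 1] * fy])

    onset_px = tuple(xy[0])
    offset_px = tuple(xy[-1])
    amplitude = distance_deg(onset_px, offset_px, geometry)
    expected = distance_deg(start_target_px, end_target_px, geometry)
    if expected == 0:
        raise ValueError("zero expected amplitude: start and end targets coincide")
    gain = amplitude / expected

    if len(samples) >= 3:
        angles = _chord_angles_deg(pts_deg)
        curvature = float(np.median(np.abs(angles))) if len(angles) else 0.0
    else:
        curvature = float("nan")

    steps = np.hypot(np.diff(pts_deg[:, 0]), np.diff(pts_deg[:, 1]))
    dts = np.diff(t)
    vels = steps / dts
    return SaccadeMetrics(
        amplitude_deg=float(amplitude),
        duration_ms=float((t[-1] - t[0]) * 1000.0),
        gain=float(gain),
        curvature_deg=curvature,
        latency_ms=float((t[0] - target_onset) * 1000.0),
        mean_velocity_deg_s=float(np.mean(vels)),
        peak_velocity_deg_s=float(np.max(vels)),
        starting_error_deg=float(distance_deg(onset_px, start_target_px, geometry)),
        landing_error_deg=float(distance_deg(offset_px, end_target_px, geometry)),
    )


def match_saccades_to_trials(
    rec: GazeRecording,
    segmentation: EventSegmentation,
    trials: pd.DataFrame,
    geometry: Optional[ScreenGeometry] = None,
    min_amplitude_deg: float = 1.0,
) -> pd.DataFrame:
    """Match each target transition to its saccade and compute metrics.

    For each consecutive pair of trials with distinct targets, the matched
    saccade is the first detected saccade with onset after the new target's
    onset and amplitude ≥ ``min_amplitude_deg``. Unmatched transitions are
    omitted. Returns one row per matched saccade with all metric columns.
    """
    geo = geometry if geometry is not None else rec.geometry
    sacc = segmentation.saccades
    rows = []
    for k in range(1, len(trials)):
        prev, cur = trials.iloc[k - 1], trials.iloc[k]
        start_t = (prev["target_x_px"], prev["target_y_px"])
        end_t = (cur["target_x_px"], cur["target_y_px"])
        if start_t == end_t:
            continue
        cand = sacc[(sacc["onset_time"] >= cur["onset"]) & (sacc["onset_time"] < cur["offset"])]
        for s in cand.itertuples():
            window = rec.samples.iloc[int(s.onset_idx) : int(s.offset_idx) + 1]
            m = saccade_metrics(window, start_t, end_t, cur["onset"], geo)
            if m.amplitude_deg >= min_amplitude_deg:
                rows.append(dict(trial_id=cur["trial_id"], **m.__dict__))
                break
    return pd.DataFrame(rows)


def main_sequence(saccades: Sequence[SaccadeMetrics] | pd.DataFrame) -> dict:
    """Least-squares main-sequence fits over a set of saccades.

    Returns slopes, intercepts and Pearson correlations for
    duration ~ amplitude (ms per deg) and peak velocity ~ amplitude
    (deg/s per deg). Requires ≥ 3 saccades and non-degenerate amplitudes.
    """
    if isinstance(saccades, pd.DataFrame):
        amp = saccades["amplitude_deg"].to_numpy(float)
        dur = saccades["duration_ms"].to_numpy(float)
        pv = saccades["peak_velocity_deg_s"].to_numpy(float)
    else:
        amp = np.array([s.amplitude_deg for s in saccades])
        dur = np.array([s.duration_ms for s in saccades])
        pv = np.array([s.peak_velocity_deg_s for s in saccades])
    if len(amp) < 3:
        raise ValueError("need at least 3 saccades for a main-sequence fit")
    if np.ptp(amp) == 0:
        raise ValueError("degenerate main-sequence input: all amplitudes equal")
    fit_dur = stats.linregress(amp, dur)
    fit_pv = stats.linregress(amp, pv)
    return dict(
        duration_slope_ms_per_deg=float(fit_dur.slope),
        duration_intercept_ms=float(fit_dur.intercept),
        duration_r=float(fit_dur.rvalue),
        duration_slope_se=float(fit_dur.stderr),
        peak_velocity_slope=float(fit_pv.slope),
        peak_velocity_intercept=float(fit_pv.intercept),
        peak_velocity_r=float(fit_pv.rvalue),
        peak_velocity_slope_se=float(fit_pv.stderr),
        n=len(amp),
    )
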