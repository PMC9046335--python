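"""Adaptive velocity-based parsing of gaze samples into fixations, saccades, gaps.

Per-sample angular velocity is the angular distance between consecutive
valid samples divided by the inter-sample time. The saccade threshold is
set adaptively per recording (i.e. per participant × condition) at

    threshold = median(v) + 5 · MAD(v),

with MAD the plain median absolute deviation (no normal-consistency
constant). Runs of above-threshold samples lasting at least 20 ms (three
sample periods at 150 Hz) are saccades; shorter spikes are relabelled
fixation; invalid samples and samples whose velocity is undefined across a
gap are labelled gap. Gaps split events: no fixation or saccade spans an
invalid sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .containers import GazeRecording, MalformedRecordingError
from .geometry import ScreenGeometry

__all__ = [
    "EventSegmentation",
    "sample_velocities",
    "adaptive_threshold",
    "classify_samples",
    "segment_recording",
]

FIXATION, SACCADE, GAP = "fixation", "saccade", "gap"


@dataclass
class EventSegmentation:
    """Per-sample labels plus extracted fixation/saccade records.

    ``labels`` has one entry per sample in {fixation, saccade, gap}.
    ``saccades`` columns: onset_idx, offset_idx, onset_time, offset_time,
    duration_ms. ``fixations`` columns: onset_idx, offset_idx, onset_time,
    offset_time, duration_ms, centroid_x_px, centroid_y_px.
    """

    labels: np.ndarray
    saccades: pd.DataFrame
    fixations: pd.DataFrame
    threshold_deg_s: float

    def counts(self) -> dict:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))


def sample_velocities(rec: GazeRecording, geometry: Optional[ScreenGeometry] = None) -> np.ndarray:
    """Per-sample angular velocity (deg/s); NaN where undefined.

    Velocity of sample *i* is attributed backward (uses the step i−1 → i).
    The first sample, invalid samples, and samples following an invalid
    sample have undefined velocity.
    """
    geo = geometry if geometry is not None else rec.geometry
    t = rec.t
    if len(t) < 2:
        raise MalformedRecordingError("need at least 2 samples to compute velocities")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise MalformedRecordingError("timestamps must be strictly increasing")
    xy = rec.xy
    dx = np.diff(xy[:, 0]) * geo.deg_per_px("horizontal")
    dy = np.diff(xy[:, 1]) * geo.deg_per_px("vertical")
    step_deg = np.hypot(dx, dy)
    v = np.full(len(t), np.nan)
    valid = rec.valid
    ok = valid[1:] & valid[:-1]
    v[1:][ok] = step_deg[ok] / dt[ok]
    return v


def adaptive_threshold(velocities: np.ndarray, n_mad: float = 5.0) -> float:
    """Median + ``n_mad``·MAD of the defined velocities (deg/s).

    MAD is the raw median absolute deviation from the median, without the
    1.4826 normal-consistency constant.
    """
    v = np.asarray(velocities, float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise MalformedRecordingError("need at least 2 defined velocities")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    return med + n_mad * mad


def classify_samples(
    rec: GazeRecording,
    velocities: np.ndarray,
    threshold: float,
    min_saccade_ms: float = 20.0,
    merge_gap_ms: float = 20.0,
) -> EventSegmentation:
    """Label every sample fixation/saccade/gap and extract event records.

    A run of consecutive above-threshold samples is a saccade if it spans
    at least ``min_saccade_ms`` of above-threshold velocity intervals
    (k·period for a run of k): three sample periods make the minimal 20 ms
    saccade at 150 Hz.
    Shorter runs are relabelled fixation. Above-threshold runs separated by
    fewer than ``merge_gap_ms`` of below-threshold (but valid) samples are
    merged first, so a one-sample velocity dip inside a saccade does not
    split it in two. Saccade onset is the first above-threshold sample of
    the (merged) run, offset the last.
    """
    if not np.isfinite(threshold):
        raise MalformedRecordingError("threshold must be finite")
    t = rec.t
    n = len(t)
    valid = rec.valid
    v = np.asarray(velocities, float)

    labels = np.empty(n, object)
    labels[~valid] = GAP
    defined = np.isfinite(v)
    above = valid & defined & (v > threshold)
    # valid samples with undefined velocity (first sample / after a gap) are
    # kept as fixation so they don't fragment surrounding fixations
    labels[valid & ~above] = FIXATION
    labels[above] = SACCADE

    period_ms = 1000.0 / rec.nominal_rate_hz
    # bridge sub-merge-gap dips between above-threshold runs, but only when
    # one side is a multi-sample run: isolated single-sample noise
    # exceedances must not chain into a spurious saccade
    max_gap = max(int(np.ceil(merge_gap_ms / period_ms)) - 1, 0)
    if max_gap > 0:
        above_idx = np.flatnonzero(above)
        run_len = {}
        i = 0
        while i < len(above_idx):
            j = i
            while j + 1 < len(above_idx) and above_idx[j + 1] == above_idx[j] + 1:
                j += 1
            length = j - i + 1
            for k in range(i, j + 1):
                run_len[above_idx[k]] = length
            i = j + 1
        for a, b in zip(above_idx[:-1], above_idx[1:]):
            if (
                1 < b - a <= max_gap + 1
                and np.all(valid[a : b + 1])
                and max(run_len[a], run_len[b]) >= 2
            ):
                labels[a:b] = SACCADE
    # k above-threshold velocities involve k+1 gaze samples
    min_run = max(int(np.ceil(min_saccade_ms / period_ms)), 1)

    # relabel too-short saccade runs as fixation
    sacc_rows = []
    i = 0
    while i < n:
        if labels[i] == SACCADE:
            j = i
            while j + 1 < n and labels[j + 1] == SACCADE:
                j += 1
            if (j - i + 1) < min_run:
                labels[i : j + 1] = FIXATION
            else:
                sacc_rows.append(
                    dict(
                        onset_idx=i,
                        offset_idx=j,
                        onset_time=t[i],
                        offset_time=t[j],
                        duration_ms=(j - i + 1) * period_ms,
                    )
                )
            i = j + 1
        else:
            i += 1

    xy = rec.xy
    fix_rows = []
    i = 0
    while i < n:
        if labels[i] == FIXATION:
            j = i
            while j + 1 < n and labels[j + 1] == FIXATION:
                j += 1
            fix_rows.append(
                dict(
                    onset_idx=i,
                    offset_idx=j,
                    onset_time=t[i],
                    offset_time=t[j],
                    duration_ms=(j - i + 1) * period_ms,
                    centroid_x_px=float(np.nanmean(xy[i : j + 1, 0])),
                    centroid_y_px=float(np.nanmean(xy[i : j + 1, 1])),
                )
            )
            i = j + 1
        else:
            i += 1

    sacc_cols = ["onset_idx", "offset_idx", "onset_time", "offset_time", "duration_ms"]
    fix_cols = sacc_cols + ["centroid_x_px", "centroid_y_px"]
    return EventSegmentation(
        labels=labels.astype(str),
        saccades=pd.DataFrame(sacc_rows, columns=sacc_cols),
        fixations=pd.DataFrame(fix_rows, columns=fix_cols),
        threshold_deg_s=float(threshold),
    )


def segment_recording(
    rec: GazeRecording,
    geometry: Optional[ScreenGeometry] = None,
    n_mad: float = 5.0,
    min_saccade_ms: float = 20.0,
) -> EventSegmentation:
    """Convenience wrapper: velocities → adaptive threshold → classification."""
    v = sample_velocities(rec, geometry)
    thr = adaptive_threshold(v, n_mad=n_mad)
    return classify_samples(rec, v, thr, min_saccade_ms=min_saccade_ms)
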