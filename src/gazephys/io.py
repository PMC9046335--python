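"""File dialects (gaze CSV, physio CSV, events CSV), config, and the pipeline.

The gaze reader speaks a Gazepoint-style CSV dialect: a time column in
seconds, gaze x/y either normalized to the screen (0–1) or already in
pixels, a 0/1 validity flag, and optional per-eye pupil diameters in mm
(the monocular diameter is the mean of the eyes available per sample).
Column names and the coordinate mode are configurable per dialect, since
exports differ between acquisition-software versions.

Times are float seconds from session start; all interval rules are
half-open [onset, offset). Written files round-trip bit-exactly in pixel
mode (floats serialised with ``repr`` precision).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import GazeRecording, PhysioTrace
from .geometry import ScreenGeometry
from .simulate import (
    AffectParams,
    CardiacParams,
    MainSequenceParams,
    PupilParams,
    SCParams,
    SimConfig,
    DEFAULT_SCREEN,
)

__all__ = [
    "GazeCsvDialect",
    "SchemaError",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_physio_csv",
    "write_physio_csv",
    "write_events_csv",
    "load_config",
    "sim_config_from_dict",
    "run_pipeline",
]

log = logging.getLogger("gazephys")


class SchemaError(ValueError):
    """A required column is missing or malformed."""


def _to_csv_exact(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV whose float cells round-trip bit-exactly.

    Python's ``repr`` emits the shortest string that parses back to the
    identical double, which pandas' default float formatting does not
    guarantee.
    """
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda x: repr(float(x)))
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class GazeCsvDialect:
    """Column map and coordinate mode for a gaze CSV export."""

    time: str = "TIME"
    x: str = "FPOGX"
    y: str = "FPOGY"
    valid: str = "FPOGV"
    pupil_left: Optional[str] = "LPMM"
    pupil_right: Optional[str] = "RPMM"
    coordinates: str = "normalized"  # "normalized" (0-1 of screen) or "px"


def read_gaze_csv(
    path: str | Path,
    dialect: GazeCsvDialect,
    geometry: ScreenGeometry,
    nominal_rate_hz: float = 150.0,
) -> GazeRecording:
    """Parse a gaze CSV into a :class:`GazeRecording`.

    Normalized coordinates are scaled by the screen resolution; the
    monocular pupil is the mean of whichever eye columns hold finite
    values. Missing required columns raise :class:`SchemaError` naming the
    column; non-monotone time raises via the recording invariant.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (dialect.time, dialect.x, dialect.y, dialect.valid):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    x = df[dialect.x].to_numpy(float)
    y = df[dialect.y].to_numpy(float)
    if dialect.coordinates == "normalized":
        x = x * geometry.width_px
        y = y * geometry.height_px
    elif dialect.coordinates != "px":
        raise SchemaError(f"unknown coordinate mode {dialect.coordinates!r}")
    eyes = []
    for col in (dialect.pupil_left, dialect.pupil_right):
        if col is not None and col in df.columns:
            eyes.append(df[col].to_numpy(float))
    if eyes:
        stacked = np.vstack(eyes)
        finite = np.isfinite(stacked)
        counts = finite.sum(axis=0)
        with np.errstate(invalid="ignore"):
            pupil = np.where(
                counts > 0, np.where(finite, stacked, 0.0).sum(axis=0) / np.maximum(counts, 1),
                np.nan,
            )
    else:
        pupil = np.full(len(df), np.nan)
    samples = pd.DataFrame(
        {
            "t": df[dialect.time].to_numpy(float),
            "x_px": x,
            "y_px": y,
            "valid": df[dialect.valid].to_numpy(float) > 0,
            "pupil_mm": pupil,
        }
    )
    return GazeRecording(samples, geometry, nominal_rate_hz=nominal_rate_hz)


def write_gaze_csv(rec: GazeRecording, path: str | Path, dialect: GazeCsvDialect) -> None:
    """Write a recording in the given dialect (inverse of :func:`read_gaze_csv`)."""
    geo = rec.geometry
    x, y = rec.xy[:, 0], rec.xy[:, 1]
    if dialect.coordinates == "normalized":
        x = x / geo.width_px
        y = y / geo.height_px
    out = {
        dialect.time: rec.t,
        dialect.x: x,
        dialect.y: y,
        dialect.valid: rec.valid.astype(int),
    }
    if dialect.pupil_left is not None:
        out[dialect.pupil_left] = rec.pupil_mm
    if dialect.pupil_right is not None:
        out[dialect.pupil_right] = rec.pupil_mm
    _to_csv_exact(pd.DataFrame(out), path)


def read_physio_csv(path: str | Path, units: str = "au") -> PhysioTrace:
    """Read a time–value CSV (columns t_s, value); rate from the median Δt."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t_s", "value"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    t = df["t_s"].to_numpy(float)
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return PhysioTrace(t=t, value=df["value"].to_numpy(float), rate_hz=rate, units=units)


def write_physio_csv(trace: PhysioTrace, path: str | Path) -> None:
    _to_csv_exact(pd.DataFrame({"t_s": trace.t, "value": trace.value}), path)


def write_events_csv(segmentation, path: str | Path) -> None:
    """Export the segmentation as a BED-like interval table (onset_s, offset_s, label)."""
    frames = []
    for label, df in (("saccade", segmentation.saccades), ("fixation", segmentation.fixations)):
        if len(df):
            frames.append(
                pd.DataFrame(
                    {"onset_s": df["onset_time"], "offset_s": df["offset_time"], "label": label}
                )
            )
    events = pd.concat(frames).sort_values("onset_s") if frames else pd.DataFrame(
        columns=["onset_s", "offset_s", "label"]
    )
    events.to_csv(path, index=False)


# ----------------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def sim_config_from_dict(d: dict, seed: Optional[int] = None) -> SimConfig:
    """Build a :class:`SimConfig` from a (possibly partial) config mapping.

    The seed must be present in the mapping or passed explicitly.
    """
    d = dict(d)
    if seed is not None:
        d["seed"] = seed
    if "seed" not in d:
        raise ValueError("simulation config requires a seed")
    geometry = (
        ScreenGeometry.from_dict(d["geometry"]) if "geometry" in d else DEFAULT_SCREEN
    )
    def sub(cls, key):
        return cls(**d[key]) if key in d else cls()

    kwargs = dict(
        seed=int(d["seed"]),
        geometry=geometry,
        main_sequence=sub(MainSequenceParams, "main_sequence"),
        pupil=sub(PupilParams, "pupil"),
        affect=sub(AffectParams, "affect"),
        cardiac=sub(CardiacParams, "cardiac"),
        sc=sub(SCParams, "sc"),
    )
    for key in (
        "rate_hz",
        "precision_sd_deg",
        "loss_prob",
        "timestamp_jitter_ms",
    ):
        if key in d:
            kwargs[key] = float(d[key])
    for key in ("accuracy_offset_deg", "saccade_latency_ms"):
        if key in d:
            kwargs[key] = tuple(float(v) for v in d[key])
    return SimConfig(**kwargs)


# ----------------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------------

def run_pipeline(config: dict, out_dir: str | Path, seed: Optional[int] = None) -> dict:
    """Simulate → detect → quality → saccades → pupil → hrv → sc, writing reports.

    Returns a summary dict (also written as ``session_summary.json``); all
    tables go to tidy CSVs under ``out_dir``. Deterministic under a fixed
    seed. Any stage failure raises with a stage-labelled message.
    """
    from . import cardio, eda, events, pupil as pupil_mod, quality, saccades as sacc_mod
    from . import simulate as sim

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = sim_config_from_dict(config.get("simulate", {}), seed=seed)
    summary: dict = {"version": __version__, "seed": cfg.seed, "config": config}
    log.info("pipeline start (seed=%d)", cfg.seed)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # re-raise with the failing stage named
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # gaze: fixation-saccade task
    rec, trials, truth = stage(
        "simulate", lambda: sim.generate_fixation_saccade_session(cfg)
    )
    write_gaze_csv(rec, out / "gaze.csv", GazeCsvDialect(coordinates="px"))
    trials.to_csv(out / "trials.csv", index=False)

    seg = stage("detect", lambda: events.segment_recording(rec))
    write_events_csv(seg, out / "events.csv")
    labelled = rec.samples.assign(label=seg.labels)
    labelled.to_csv(out / "gaze_labelled.csv", index=False)

    qrep = stage("quality", lambda: quality.quality_report(rec, trials, seg))
    qrep.to_csv(out / "quality.csv", index=False)
    stats = quality.inter_sample_stats(rec)
    summary["sampling"] = dataclasses.asdict(stats)
    summary["quality_means"] = {
        k: float(np.nanmean(qrep[k])) for k in ("a_h", "a_v", "a_g", "p_h", "p_v", "p_g", "loss")
    }
    summary["n_saccades_detected"] = int(len(seg.saccades))
    summary["n_saccades_true"] = int(len(truth.saccades))

    smet = stage(
        "saccades", lambda: sacc_mod.match_saccades_to_trials(rec, seg, trials)
    )
    smet.to_csv(out / "saccade_metrics.csv", index=False)
    if len(smet) >= 3 and np.ptp(smet["amplitude_deg"]) > 0:
        summary["main_sequence"] = sacc_mod.main_sequence(smet)

    # pupil: PLR task
    prec, stim, ptruth = stage("pupil", lambda: sim.generate_plr_session(cfg))
    trace = prec.samples[["t", "pupil_mm"]].copy()
    trace = pupil_mod.clean_range(trace)
    trace = pupil_mod.interpolate_gaps(trace)
    corrected = pupil_mod.baseline_correct(trace, stim["onset"].to_numpy())
    corrected[["t", "trial", "corrected_mm"]].to_csv(out / "pupil_corrected.csv", index=False)
    summary["plr"] = stage("plr", lambda: pupil_mod.plr_summary(corrected, stim))

    # cardio
    nn_true, ctruth = stage("hrv", lambda: sim.generate_nn_series(cfg, duration_s=300.0))
    pulse = sim.render_pulse_waveform(nn_true, rate_hz=cfg.rate_hz)
    write_physio_csv(pulse, out / "pulse.csv")
    filt = cardio.lowpass(pulse)
    beats = cardio.detect_beats(filt)
    nn = cardio.build_nn_series(beats)
    pd.DataFrame(
        {
            "beat_time_s": nn.beat_times[1:],
            "rr_ms": nn.rr_ms,
            "flag": nn.artifact.astype(int),
            "nn_ms": nn.nn_ms,
        }
    ).to_csv(out / "nn_series.csv", index=False)
    summary["hrv"] = dataclasses.asdict(cardio.hrv_metrics(nn))

    # skin conductance
    event_times = [20.0, 60.0, 100.0]
    sc_trace, struth = stage(
        "sc", lambda: sim.generate_sc_trace(cfg, event_times, duration_s=130.0)
    )
    write_physio_csv(sc_trace, out / "sc.csv")
    sc10 = eda.preprocess_sc(sc_trace)
    responses = [eda.event_response(sc10, e) for e in event_times]
    summary["sc"] = {
        "global_mean_us": float(np.mean(sc10.value)),
        "event_responses_us": responses,
    }

    with open(out / "session_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    log.info("pipeline complete: %s", out)
    return summary
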