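"""Core in-memory containers shared across the pipeline.

Tabular data (trials, stimuli, reports) are plain :class:`pandas.DataFrame`
objects with documented column names; the classes here wrap the time series
that need invariant checks and attached metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry

__all__ = ["GazeRecording", "PhysioTrace", "NNSeries", "MalformedRecordingError"]


class MalformedRecordingError(ValueError):
    """Recording violates a structural invariant (e.g. non-increasing time)."""


@dataclass
class GazeRecording:
    """Timestamped gaze/pupil samples bound to a screen geometry.

    ``samples`` columns:

    t : float
        Seconds from session start, strictly increasing.
    x_px, y_px : float
        Gaze point in screen pixels (origin top-left, y down). May be NaN
        on invalid samples.
    valid : bool
        Device validity flag; invalid samples are treated as gaps.
    pupil_mm : float, optional
        Monocular pupil diameter in millimetres (NaN when unavailable).
    """

    samples: pd.DataFrame
    geometry: ScreenGeometry
    nominal_rate_hz: float = 150.0
    participant: str = "sim"
    condition: str = "chinrest"

    def __post_init__(self) -> None:
        required = {"t", "x_px", "y_px", "valid"}
        missing = required - set(self.samples.columns)
        if missing:
            raise MalformedRecordingError(f"gaze samples missing columns: {sorted(missing)}")
        t = self.samples["t"].to_numpy(float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise MalformedRecordingError("timestamps must be strictly increasing")
        if not (self.nominal_rate_hz > 0):
            raise MalformedRecordingError("nominal_rate_hz must be positive")
        if "pupil_mm" not in self.samples.columns:
            self.samples = self.samples.assign(pupil_mm=np.nan)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def t(self) -> np.ndarray:
        return self.samples["t"].to_numpy(float)

    @property
    def xy(self) -> np.ndarray:
        return self.samples[["x_px", "y_px"]].to_numpy(float)

    @property
    def valid(self) -> np.ndarray:
        return self.samples["valid"].to_numpy(bool)

    @property
    def pupil_mm(self) -> np.ndarray:
        return self.samples["pupil_mm"].to_numpy(float)


@dataclass
class PhysioTrace:
    """Uniformly sampled physiological time series (pulse waveform or SC)."""

    t: np.ndarray
    value: np.ndarray
    rate_hz: float
    units: str = "au"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.value = np.asarray(self.value, float)
        if self.t.shape != self.value.shape:
            raise MalformedRecordingError("t and value must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise MalformedRecordingError("trace timestamps must be strictly increasing")
        if not (self.rate_hz > 0):
            raise MalformedRecordingError("rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class NNSeries:
    """Beat times with RR intervals, artifact flags, and corrected NN intervals.

    ``rr_ms[k]`` is the interval between ``beat_times[k]`` and
    ``beat_times[k+1]``; ``nn_ms`` is the artifact-corrected series (equal to
    ``rr_ms`` where no flag is set).
    """

    beat_times: np.ndarray
    rr_ms: np.ndarray = field(default=None)  # type: ignore[assignment]
    artifact: Optional[np.ndarray] = None
    nn_ms: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, float)
        if len(self.beat_times) > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise MalformedRecordingError("beat times must be strictly increasing")
        if self.rr_ms is None:
            self.rr_ms = np.diff(self.beat_times) * 1000.0
        else:
            self.rr_ms = np.asarray(self.rr_ms, float)
        if np.any(self.rr_ms <= 0):
            raise MalformedRecordingError("RR intervals must be positive")
        if self.artifact is not None:
            self.artifact = np.asarray(self.artifact, bool)
        if self.nn_ms is not None:
            self.nn_ms = np.asarray(self.nn_ms, float)

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    def intervals(self) -> np.ndarray:
        """Corrected NN intervals if available, else raw RR intervals (ms)."""
        return self.nn_ms if self.nn_ms is not None else self.rr_ms
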