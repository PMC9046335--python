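"""Display/viewing geometry and pixel ↔ degree-of-visual-angle conversion.

A remote eye-tracker reports gaze in screen pixels; data-quality metrics
(accuracy, precision) and saccade metrics are expressed in degrees of visual
angle. The conversion depends on the physical screen size, its resolution,
and the viewing distance.

Two conversions are distinguished:

* the *full angular extent* of an on-screen length uses the exact
  arctangent form ``2·atan(size / (2·distance))``;
* small on-screen extents use the central linear approximation
  ``extent_px · (axis angular extent / axis pixel count)``, which is the
  arithmetic behind rules of thumb like "40 px ≈ 1°" on a typical desktop
  setup.

Coordinates follow the screen convention: origin top-left, x rightward,
y downward, in (continuous) pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Tuple

__all__ = [
    "GeometryError",
    "ScreenGeometry",
    "angular_extent",
    "px_to_deg",
    "distance_deg",
]

Axis = Literal["horizontal", "vertical"]


class GeometryError(ValueError):
    """Invalid screen geometry or conversion request."""


def angular_extent(size_cm: float, distance_cm: float) -> float:
    """Full angular extent, in degrees, of a length seen from a distance.

    Parameters
    ----------
    size_cm
        Physical extent on the screen plane (cm), centered on the line of
        sight. Must be non-negative.
    distance_cm
        Viewing distance (cm), strictly positive.

    Returns
    -------
    float
        ``2·atan(size_cm / (2·distance_cm))`` in degrees; 0 iff size is 0.
    """
    if distance_cm <= 0:
        raise GeometryError(f"viewing distance must be positive, got {distance_cm}")
    if size_cm < 0:
        raise GeometryError(f"extent must be non-negative, got {size_cm}")
    return math.degrees(2.0 * math.atan2(size_cm, 2.0 * distance_cm))


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen dimensions, resolution, and viewing distance.

    All fields must be strictly positive. The defaults are free; use
    :func:`ScreenGeometry.from_dict` to build one from a config mapping.
    """

    width_cm: float
    height_cm: float
    width_px: int
    height_px: int
    distance_cm: float

    def __post_init__(self) -> None:
        for name in ("width_cm", "height_cm", "width_px", "height_px", "distance_cm"):
            value = getattr(self, name)
            if not (value > 0):
                raise GeometryError(f"{name} must be strictly positive, got {value!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenGeometry":
        return cls(
            width_cm=float(d["width_cm"]),
            height_cm=float(d["height_cm"]),
            width_px=int(d["width_px"]),
            height_px=int(d["height_px"]),
            distance_cm=float(d["distance_cm"]),
        )

    def to_dict(self) -> dict:
        return {
            "width_cm": self.width_cm,
            "height_cm": self.height_cm,
            "width_px": self.width_px,
            "height_px": self.height_px,
            "distance_cm": self.distance_cm,
        }

    @property
    def width_deg(self) -> float:
        """Full horizontal angular extent of the screen (degrees)."""
        return angular_extent(self.width_cm, self.distance_cm)

    @property
    def height_deg(self) -> float:
        """Full vertical angular extent of the screen (degrees)."""
        return angular_extent(self.height_cm, self.distance_cm)

    def deg_per_px(self, axis: Axis) -> float:
        """Linear conversion factor (degrees per pixel) along one axis."""
        if axis == "horizontal":
            return self.width_deg / self.width_px
        if axis == "vertical":
            return self.height_deg / self.height_px
        raise GeometryError(f"unknown axis {axis!r}; expected 'horizontal' or 'vertical'")


def px_to_deg(extent_px: float, geometry: ScreenGeometry, axis: Axis = "horizontal") -> float:
    """Convert an on-screen pixel extent to degrees (central linear approximation).

    Proportional to ``extent_px``; converting the full axis pixel count
    returns the exact axis angular extent.
    """
    if extent_px < 0:
        raise GeometryError(f"extent_px must be non-negative, got {extent_px}")
    return extent_px * geometry.deg_per_px(axis)


def distance_deg(
    a: Tuple[float, float], b: Tuple[float, float], geometry: ScreenGeometry
) -> float:
    """Angular (Euclidean) distance between two pixel points, in degrees.

    Each axis is converted to degrees with its own linear factor, then the
    Euclidean norm is taken — the "global/Euclidean" distance used for
    accuracy and saccade amplitude.
    """
    ax, ay = a
    bx, by = b
    if not all(math.isfinite(v) for v in (ax, ay, bx, by)):
        raise GeometryError("points must be finite")
    dx = (ax - bx) * geometry.deg_per_px("horizontal")
    dy = (ay - by) * geometry.deg_per_px("vertical")
    return math.hypot(dx, dy)
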