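"""ROI rectangles, mirroring about the backbone axis, and RGB-to-thermal mapping.

The operator selects ROI #1 on the RGB photograph — the region where the
brace is prescribed to exert its thrust.  ROI #2, the within-patient
control, is constructed automatically as the mirror image of ROI #1 about
the backbone axis (modeled as a single vertical pixel column).  Both
rectangles are then mapped onto the much coarser thermal grid.

Rectangles are half-open: ``[x0, x0 + w) x [y0, y0 + h)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .imaging_io import ImagePair, ThermalFrame

__all__ = ["GeometryError", "Rect", "RoiPair", "mirror_roi", "map_to_thermal",
           "extract", "load_roi_config"]


class GeometryError(ValueError):
    """An ROI falls outside its frame."""


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle ``[x0, x0+w) x [y0, y0+h)``."""

    x0: int
    y0: int
    w: int
    h: int
    frame: Literal["rgb", "thermal"] = "rgb"

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0:
            raise GeometryError(f"rect origin ({self.x0}, {self.y0}) negative")
        if self.w <= 0 or self.h <= 0:
            raise GeometryError(f"rect extent ({self.w}, {self.h}) not positive")

    @property
    def x1(self) -> int:
        return self.x0 + self.w

    @property
    def y1(self) -> int:
        return self.y0 + self.h

    def contains(self, other: "Rect") -> bool:
        return (self.x0 <= other.x0 and self.y0 <= other.y0
                and other.x1 <= self.x1 and other.y1 <= self.y1)


@dataclass(frozen=True)
class RoiPair:
    """ROI #1 (pressure region), ROI #2 (mirror reference) and the axis column.

    The two rectangles must have identical extents and be reflections of
    each other about the vertical line ``x = axis_x``.
    """

    roi1: Rect
    roi2: Rect
    axis_x: int

    def __post_init__(self) -> None:
        if (self.roi1.w, self.roi1.h) != (self.roi2.w, self.roi2.h):
            raise GeometryError("ROI #1 and ROI #2 must have identical extents")
        expected = 2 * self.axis_x - self.roi1.x0 - self.roi1.w
        if self.roi2.x0 != expected or self.roi2.y0 != self.roi1.y0:
            raise GeometryError(
                f"ROI #2 at x0={self.roi2.x0} is not the mirror of ROI #1 "
                f"about axis x={self.axis_x} (expected x0={expected})"
            )


def mirror_roi(roi1: Rect, axis_x: int, frame_width: int | None = None) -> Rect:
    """Reflect *roi1* about the vertical line ``x = axis_x``.

    With the half-open convention the reflected origin is
    ``x0' = 2*axis_x - x0 - w`` (the right edge maps to the left edge).

    Raises
    ------
    GeometryError
        If the reflection exits the frame on the left, or on the right when
        *frame_width* is given.
    """
    x0m = 2 * axis_x - roi1.x0 - roi1.w
    if x0m < 0:
        raise GeometryError(
            f"mirrored ROI exits frame on the left by {-x0m} px "
            f"(x0'={x0m}; axis_x={axis_x})"
        )
    if frame_width is not None and x0m + roi1.w > frame_width:
        raise GeometryError(
            f"mirrored ROI exits frame on the right by "
            f"{x0m + roi1.w - frame_width} px"
        )
    return Rect(x0m, roi1.y0, roi1.w, roi1.h, roi1.frame)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def map_to_thermal(roi: Rect, pair: ImagePair) -> Rect:
    """Map an RGB-frame rectangle onto the thermal grid.

    The origin is floored and the extent rounded half-up, so the mapping is
    platform-independent; degenerate scaled extents are promoted to one
    pixel and the result is clipped to the thermal bounds.
    """
    if roi.frame != "rgb":
        raise GeometryError("map_to_thermal expects an RGB-frame rect")
    if roi.x1 > pair.rgb.width or roi.y1 > pair.rgb.height:
        raise GeometryError(
            f"ROI ({roi.x0},{roi.y0},{roi.w},{roi.h}) exceeds RGB frame "
            f"{pair.rgb.width}x{pair.rgb.height}"
        )
    tw, th = pair.thermal.width, pair.thermal.height
    x0 = min(math.floor(roi.x0 * pair.scale_x), tw - 1)
    y0 = min(math.floor(roi.y0 * pair.scale_y), th - 1)
    w = max(1, _round_half_up(roi.w * pair.scale_x))
    h = max(1, _round_half_up(roi.h * pair.scale_y))
    w = min(w, tw - x0)
    h = min(h, th - y0)
    return Rect(x0, y0, w, h, "thermal")


def extract(frame: ThermalFrame, roi: Rect) -> np.ndarray:
    """Copy the ``h x w`` temperature sub-grid covered by a thermal-frame ROI."""
    if roi.frame != "thermal":
        raise GeometryError("extract expects a thermal-frame rect")
    if roi.x1 > frame.width or roi.y1 > frame.height:
        raise GeometryError(
            f"ROI ({roi.x0},{roi.y0},{roi.w},{roi.h}) exceeds thermal frame "
            f"{frame.width}x{frame.height}"
        )
    return frame.temperatures[roi.y0:roi.y1, roi.x0:roi.x1].copy()


def load_roi_config(path: str) -> list[RoiPair]:
    """Load one or more ROI pairs from a JSON config.

    The config is either a single object or a list of objects of the form
    ``{"roi1": {"x0":..,"y0":..,"w":..,"h":..}, "axis_x":.., "frame":"rgb"}``;
    double-curve patients contribute two pairs.  ROI #2 is constructed by
    mirroring, never read from the file.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    pairs = []
    for entry in data:
        r = entry["roi1"]
        frame = entry.get("frame", "rgb")
        roi1 = Rect(int(r["x0"]), int(r["y0"]), int(r["w"]), int(r["h"]), frame)
        axis_x = int(entry["axis_x"])
        roi2 = mirror_roi(roi1, axis_x)
        pairs.append(RoiPair(roi1=roi1, roi2=roi2, axis_x=axis_x))
    return pairs
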