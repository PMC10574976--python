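"""Reading and writing the image pairs the pipeline consumes.

A capture session produces two co-registered frames of the patient's back:
a high-resolution RGB photograph (used only for operator ROI selection) and
a low-resolution grid of calibrated skin temperatures from the infrared
camera.  This module converts both on-disk representations into the
in-memory containers the rest of the pipeline works with.

Conventions (used everywhere in the package):

* pixel coordinates are 0-based, ``x`` = column, ``y`` = row, origin at the
  top-left;
* the canonical thermal on-disk format is a comma-separated text matrix of
  degrees Celsius, one image row per line, optionally accompanied by a JSON
  metadata sidecar ``<name>.meta.json``;
* a second accepted dialect is a 16-bit single-channel PNG/TIFF of raw
  counts plus an affine calibration (``T = offset + scale * count``) given
  either as a ``<name>.calib.json`` sidecar or passed explicitly.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from PIL import Image

__all__ = [
    "DEFAULT_EMISSIVITY",
    "FormatError",
    "RegistrationError",
    "ThermalFrame",
    "RgbFrame",
    "ImagePair",
    "read_thermal",
    "write_thermal",
    "read_rgb",
    "write_rgb",
    "make_pair",
]

#: Emissivity of human skin in the 3-15 um band; carried as metadata only
#: (the camera is assumed to output already-calibrated temperatures).
DEFAULT_EMISSIVITY = 0.97

#: Default acquisition metadata for frames read without a sidecar.
DEFAULT_META: dict = {
    "emissivity": DEFAULT_EMISSIVITY,
    "ambient_c": 21.0,       # mid-point of the 19-23 degC operating room range
    "distance_m": 1.0,       # camera-to-patient distance of the protocol
    "quantization_c": 0.1,   # 100 mK thermal sensitivity
}


class FormatError(ValueError):
    """Malformed thermal/RGB input (ragged rows, bad cells, missing calibration)."""


class RegistrationError(ValueError):
    """RGB and thermal frames cannot be registered by pure scaling."""


@dataclass(frozen=True)
class ThermalFrame:
    """A 2D grid of calibrated temperatures in degrees Celsius.

    Parameters
    ----------
    temperatures
        Row-major ``(height, width)`` float array of degC values.
    meta
        Acquisition metadata: ``emissivity`` (dimensionless, in (0, 1]),
        ``ambient_c``, ``distance_m``, ``quantization_c``.
    """

    temperatures: np.ndarray
    meta: dict = field(default_factory=lambda: dict(DEFAULT_META))

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 2 or t.size == 0:
            raise FormatError("temperature grid must be a non-empty 2D array")
        if not np.all(np.isfinite(t)):
            raise FormatError("temperature grid contains non-finite values")
        emissivity = self.meta.get("emissivity", DEFAULT_EMISSIVITY)
        if not (0.0 < emissivity <= 1.0):
            raise ValueError(f"emissivity {emissivity} outside (0, 1]")
        object.__setattr__(self, "temperatures", t)

    @property
    def height(self) -> int:
        return self.temperatures.shape[0]

    @property
    def width(self) -> int:
        return self.temperatures.shape[1]


@dataclass(frozen=True)
class RgbFrame:
    """A three-channel ``(height, width, 3)`` grid of intensities in [0, 255]."""

    channels: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.channels)
        if c.ndim != 3 or c.shape[2] != 3 or c.size == 0:
            raise FormatError("RGB grid must have shape (height, width, 3)")
        if c.min() < 0 or c.max() > 255:
            raise FormatError("RGB intensities must lie in [0, 255]")
        object.__setattr__(self, "channels", c)

    @property
    def height(self) -> int:
        return self.channels.shape[0]

    @property
    def width(self) -> int:
        return self.channels.shape[1]


@dataclass(frozen=True)
class ImagePair:
    """A co-registered RGB/thermal pair with the thermal/RGB scale factors.

    Registration is pure anisotropic scaling: both frames come from one
    attached-to-smartphone device, so no translation or rotation is modeled.
    """

    rgb: RgbFrame
    thermal: ThermalFrame
    scale_x: float
    scale_y: float

    def __post_init__(self) -> None:
        if not (0.0 < self.scale_x <= 1.0 and 0.0 < self.scale_y <= 1.0):
            raise RegistrationError(
                f"scale factors ({self.scale_x}, {self.scale_y}) outside (0, 1]"
            )


# ---------------------------------------------------------------------------
# thermal I/O


def _read_thermal_text(path: str) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = [c.strip() for c in line.replace("\t", ",").split(",")]
            parsed = []
            for colno, cell in enumerate(cells, start=1):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at row {lineno}, "
                        f"column {colno}"
                    ) from None
            rows.append(parsed)
    if not rows:
        raise FormatError(f"{path}: empty thermal matrix")
    width = len(rows[0])
    for i, r in enumerate(rows, start=1):
        if len(r) != width:
            raise FormatError(
                f"{path}: ragged matrix — row {i} has {len(r)} cells, "
                f"expected {width}"
            )
    return np.array(rows, dtype=float)


def _sidecar(path: str, suffix: str) -> str:
    base, _ = os.path.splitext(path)
    return base + suffix


def read_thermal(path: str, calibration: Mapping | None = None) -> ThermalFrame:
    """Read a thermal frame from disk, in either accepted dialect.

    ``.csv``/``.txt`` files are parsed as delimited matrices of degC values.
    16-bit single-channel images are converted with the affine calibration
    ``T = offset_c + scale_c_per_count * count``, taken from *calibration*
    or from a ``<name>.calib.json`` sidecar.

    Raises
    ------
    FormatError
        For ragged rows, non-numeric cells, or an integer image without
        calibration.
    """
    ext = os.path.splitext(path)[1].lower()
    meta = dict(DEFAULT_META)
    if ext in {".csv", ".txt"}:
        temps = _read_thermal_text(path)
        meta_path = _sidecar(path, ".meta.json")
        if os.path.exists(meta_path):
            with open(meta_path, "r", encoding="utf-8") as fh:
                meta.update(json.load(fh))
        return ThermalFrame(temps, meta)

    # integer-count image dialect
    if calibration is None:
        calib_path = _sidecar(path, ".calib.json")
        if not os.path.exists(calib_path):
            raise FormatError(
                f"{path}: integer-count thermal image requires calibration "
                f"(offset/scale); no sidecar {calib_path!r} found"
            )
        with open(calib_path, "r", encoding="utf-8") as fh:
            calibration = json.load(fh)
    offset = float(calibration.get("offset_c", calibration.get("offset", 0.0)))
    scale = float(
        calibration.get("scale_c_per_count", calibration.get("scale", 1.0))
    )
    for key in ("emissivity", "ambient_c", "distance_m", "quantization_c"):
        if key in calibration:
            meta[key] = calibration[key]
    try:
        img = Image.open(path)
        counts = np.asarray(img, dtype=float)
    except OSError as exc:
        raise FormatError(f"{path}: unreadable thermal image ({exc})") from exc
    if counts.ndim != 2:
        raise FormatError(f"{path}: thermal image must be single-channel")
    return ThermalFrame(offset + scale * counts, meta)


def write_thermal(frame: ThermalFrame, path: str, write_meta: bool = True) -> None:
    """Write a thermal frame in the canonical delimited-text dialect.

    Full float precision is used so a write/read round trip reproduces the
    grid exactly.
    """
    np.savetxt(path, frame.temperatures, fmt="%.17g", delimiter=",")
    if write_meta:
        with open(_sidecar(path, ".meta.json"), "w", encoding="utf-8") as fh:
            json.dump(frame.meta, fh, indent=1)


def read_rgb(path: str) -> RgbFrame:
    """Read a PNG/JPEG/TIFF photograph; grayscale sources are replicated
    across the three channels."""
    try:
        img = Image.open(path)
        img = img.convert("RGB")
        arr = np.asarray(img, dtype=np.uint8)
    except OSError as exc:
        raise IOError(f"{path}: unreadable RGB image ({exc})") from exc
    return RgbFrame(arr)


def write_rgb(frame: RgbFrame, path: str) -> None:
    Image.fromarray(np.asarray(frame.channels, dtype=np.uint8), "RGB").save(path)


def make_pair(rgb: RgbFrame, thermal: ThermalFrame) -> ImagePair:
    """Register an RGB/thermal pair by pure anisotropic scaling.

    The two frames are assumed co-registered by the capture device, so the
    only degrees of freedom are the two scale factors
    ``thermal.width / rgb.width`` and ``thermal.height / rgb.height``.
    Aspect ratios differing by more than 1% indicate the frames do not
    depict the same field of view.
    """
    scale_x = thermal.width / rgb.width
    scale_y = thermal.height / rgb.height
    if not math.isclose(scale_x, scale_y, rel_tol=0.01):
        raise RegistrationError(
            f"aspect-ratio mismatch: thermal/rgb scales are x={scale_x:.6g}, "
            f"y={scale_y:.6g} (differ by more than 1%)"
        )
    return ImagePair(rgb=rgb, thermal=thermal, scale_x=scale_x, scale_y=scale_y)
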