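"""Synthetic thermal-phantom generator.

Produces paired RGB/thermal back images with the statistical structure the
assessment method assumes, so the whole pipeline is testable without
patient data.  The forward model is deliberately minimal:

* a smooth baseline skin-temperature field (constant plus a vertical
  linear trend, emulating the natural head-to-hip gradient);
* a localized warm region where brace pressure acted, modeled as an
  isotropic Gaussian bump of peak amplitude ``delta_t_c`` — the
  thermoelastic temperature elevation is represented only through this
  pressure-proportional amplitude, not through tissue constants or
  stress/strain tensors;
* a sensor model with three error components matching a low-cost
  smartphone-attached camera: additive Gaussian noise (sd = the 100 mK
  thermal sensitivity), a per-image uniform bias within the +/-3 degC
  accuracy band, and quantization to 0.1 degC steps.

ROI #1 is the box covering the hot spot (+/- 2 sigma); ROI #2 is its
mirror about the vertical midline of the frame (the phantom's backbone
axis).  An *inadequate* phantom is generated with ``delta_t_c = 0``:
nothing but baseline and sensor error distinguishes the two ROIs.

Emissivity never enters the forward model — the camera is assumed to
output calibrated temperatures — and is carried as metadata only.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import ScoreRecord
from .imaging_io import (DEFAULT_META, ImagePair, RgbFrame, ThermalFrame,
                         make_pair, write_rgb, write_thermal)
from .roi_geometry import Rect, RoiPair, extract, map_to_thermal, mirror_roi
from .thermal_processing import partition_vector, to_grayscale_joint
from .decision_stats import student_t_test

__all__ = ["PhantomConfig", "PhantomRecord", "generate_phantom",
           "generate_study", "study_to_scores", "write_study"]

#: Flat skin tone used for the RGB companion image.
_SKIN_RGB = (224, 172, 105)


class ConfigError(ValueError):
    """Phantom configuration places the hot spot (or its mirror) off-frame."""


@dataclass(frozen=True)
class PhantomConfig:
    """Forward-model parameters for one synthetic back image.

    Defaults mirror the acquisition hardware (1440x1080 RGB alongside a
    160x120 thermal grid, 100 mK sensitivity and quantization, 3 degC
    accuracy band) and a physiologically plausible back: 33 degC baseline
    with a small vertical trend.
    """

    rgb_size: tuple[int, int] = (1440, 1080)        # (width, height)
    thermal_size: tuple[int, int] = (160, 120)
    baseline_c: float = 33.0
    gradient_c_per_px: float = 0.002                 # degC per thermal row
    hotspot_center: tuple[int, int] = (40, 60)       # (x, y), thermal px
    hotspot_sigma_px: float = 6.0
    delta_t_c: float = 1.0                           # 0 => inadequate pressure
    noise_sd_c: float = 0.1                          # 100 mK sensitivity
    quantization_c: float = 0.1
    bias_range_c: float = 3.0                        # accuracy: U(-3, +3) offset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_t_c < 0 or self.noise_sd_c < 0:
            raise ValueError("delta_t_c and noise_sd_c must be non-negative")
        if min(*self.rgb_size, *self.thermal_size) <= 0:
            raise ValueError("frame sizes must be positive")


@dataclass(frozen=True)
class PhantomRecord:
    """One generated instance: the image pair, its ROIs and ground truth."""

    pair: ImagePair
    rois: RoiPair
    label: int
    true_delta_t_c: float


def _hotspot_box_thermal(config: PhantomConfig) -> Rect:
    cx, cy = config.hotspot_center
    half = int(round(2.0 * config.hotspot_sigma_px))
    x0, y0 = cx - half, cy - half
    w = h = 2 * half
    tw, th = config.thermal_size
    if x0 < 0 or y0 < 0 or x0 + w > tw or y0 + h > th:
        raise ConfigError(
            f"hot-spot box ({x0},{y0},{w},{h}) exits the {tw}x{th} thermal frame"
        )
    return Rect(x0, y0, w, h, "thermal")


def generate_phantom(config: PhantomConfig, adequacy_cutoff_c: float = 0.5,
                     label: int | None = None) -> PhantomRecord:
    """Generate one synthetic RGB/thermal pair with its ROI pair and label.

    The thermal grid is ``baseline + gradient*y + delta_t * exp(-d^2 / (2
    sigma^2)) + bias + noise``, quantized to ``quantization_c`` steps;
    temperatures are sampled at integer pixel coordinates.  Deterministic
    given ``config.seed``.

    By default the label is 1 iff ``delta_t_c >= adequacy_cutoff_c``; an
    explicit *label* overrides this (used by study generators that assign
    labels by intended class).
    """
    tw, th = config.thermal_size
    rw, rh = config.rgb_size
    rng = np.random.default_rng(config.seed)

    x = np.arange(tw)[None, :]
    y = np.arange(th)[:, None]
    cx, cy = config.hotspot_center
    temps = (config.baseline_c
             + config.gradient_c_per_px * y
             + np.zeros((th, tw)))
    if config.delta_t_c > 0:
        d2 = (x - cx) ** 2.0 + (y - cy) ** 2.0
        temps = temps + config.delta_t_c * np.exp(
            -d2 / (2.0 * config.hotspot_sigma_px ** 2)
        )
    # the bias draw is always consumed (even at range 0) so phantoms that
    # differ only in bias_range_c share identical noise fields
    temps = temps + config.bias_range_c * rng.uniform(-1.0, 1.0)
    if config.noise_sd_c > 0:
        temps = temps + rng.normal(0.0, config.noise_sd_c, size=temps.shape)
    if config.quantization_c > 0:
        temps = np.round(temps / config.quantization_c) * config.quantization_c

    meta = dict(DEFAULT_META)
    meta["quantization_c"] = config.quantization_c
    thermal = ThermalFrame(temps, meta)
    rgb = RgbFrame(np.full((rh, rw, 3), _SKIN_RGB, dtype=np.uint8))
    pair = make_pair(rgb, thermal)

    # ROI #1 covers the hot-spot box; coordinates are expressed in the RGB
    # frame (where the operator would draw them) by inverse scaling.
    box = _hotspot_box_thermal(config)
    sx, sy = rw / tw, rh / th
    roi1 = Rect(int(round(box.x0 * sx)), int(round(box.y0 * sy)),
                int(round(box.w * sx)), int(round(box.h * sy)), "rgb")
    axis_x = rw // 2
    roi2 = mirror_roi(roi1, axis_x, frame_width=rw)
    rois = RoiPair(roi1=roi1, roi2=roi2, axis_x=axis_x)

    if label is None:
        label = int(config.delta_t_c >= adequacy_cutoff_c)
    return PhantomRecord(pair=pair, rois=rois, label=label,
                         true_delta_t_c=config.delta_t_c)


def generate_study(n_adequate: int, n_inadequate: int,
                   delta_t_adequate_c: float = 1.0, seed: int = 0,
                   base_config: PhantomConfig | None = None,
                   delta_t_jitter_c: float = 0.0) -> list[PhantomRecord]:
    """Generate a labeled study: adequate phantoms first, then inadequate.

    Adequate records get ``delta_t_c = delta_t_adequate_c`` (optionally
    jittered by U(-jitter, +jitter), clipped at 0); inadequate records get
    ``delta_t_c = 0``.  Record ``i`` uses seed ``seed + i``, so two calls
    with the same arguments produce identical datasets.  Labels follow the
    intended class, which coincides with the amplitude-cutoff rule whenever
    ``0 < cutoff <= delta_t_adequate_c``.
    """
    if n_adequate < 0 or n_inadequate < 0:
        raise ValueError("counts must be non-negative")
    base = base_config or PhantomConfig()
    records = []
    for i in range(n_adequate + n_inadequate):
        adequate = i < n_adequate
        delta = delta_t_adequate_c if adequate else 0.0
        if adequate and delta_t_jitter_c > 0:
            jrng = np.random.default_rng(seed + i + 1_000_003)
            delta = max(0.0, delta + jrng.uniform(-delta_t_jitter_c,
                                                  delta_t_jitter_c))
        cfg = replace(base, delta_t_c=delta, seed=seed + i)
        records.append(generate_phantom(cfg, label=int(adequate)))
    return records


def study_to_scores(records: list[PhantomRecord], n_rows: int = 4,
                    n_cols: int = 4) -> list[ScoreRecord]:
    """Run the assessment pipeline (without thresholding) on each record.

    Emits the (p-value, warm-direction flag, label) triple the evaluation
    machinery consumes.
    """
    scores = []
    for rec in records:
        t1 = map_to_thermal(rec.rois.roi1, rec.pair)
        t2 = map_to_thermal(rec.rois.roi2, rec.pair)
        g1, g2 = to_grayscale_joint(extract(rec.pair.thermal, t1),
                                    extract(rec.pair.thermal, t2))
        v1 = partition_vector(g1, n_rows, n_cols)
        v2 = partition_vector(g2, n_rows, n_cols)
        res = student_t_test(v1, v2, check_normality=False)
        scores.append(ScoreRecord(p_value=res.p_value,
                                  direction_ok=res.mean1 > res.mean2,
                                  label=rec.label))
    return scores


def write_study(records: list[PhantomRecord], out_dir: str) -> None:
    """Write a phantom study to *out_dir*.

    Per record: ``thermal_XXX.csv`` (+ metadata sidecar), ``rgb_XXX.png``
    and ``roi_XXX.json``; plus a ``manifest.csv`` with labels and true
    hot-spot amplitudes.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        stem = f"{i:03d}"
        write_thermal(rec.pair.thermal, os.path.join(out_dir, f"thermal_{stem}.csv"))
        write_rgb(rec.pair.rgb, os.path.join(out_dir, f"rgb_{stem}.png"))
        roi = {"roi1": {"x0": rec.rois.roi1.x0, "y0": rec.rois.roi1.y0,
                        "w": rec.rois.roi1.w, "h": rec.rois.roi1.h},
               "axis_x": rec.rois.axis_x, "frame": "rgb"}
        with open(os.path.join(out_dir, f"roi_{stem}.json"), "w",
                  encoding="utf-8") as fh:
            json.dump(roi, fh, indent=1)
        rows.append({"index": i, "label": rec.label,
                     "true_delta_t_c": rec.true_delta_t_c})
    with open(os.path.join(out_dir, "manifest.csv"), "w", newline="",
              encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=["index", "label", "true_delta_t_c"])
        writer.writeheader()
        writer.writerows(rows)
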