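"""Pixel-size calibration from the imaged 25 mm reference sphere.

A radio-opaque sphere of known diameter sits in the field of view of
every acquisition. Its projected disc in the label mask yields the
physical pixel pitch: the per-frame area-equivalent diameter
2·sqrt(area/π) is averaged over the sequence (the sphere is static, so
averaging suppresses per-frame rasterisation noise) and the isotropic
scale is 25 mm divided by that mean diameter in pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import CalibrationError, ValidationError
from .labels import LABEL_SCHEME, SPHERE_DIAMETER_MM, LandmarkLabel
from .volume import PseudoVolume

__all__ = ["CalibrationResult", "estimate_sphere_diameter", "mm_per_pixel", "calibrate"]


@dataclass(frozen=True)
class CalibrationResult:
    """Sphere diameter estimates and the derived millimetre-per-pixel scale."""

    diameter_px: tuple[float, ...]  # per analysed frame
    frames_used: tuple[int, ...]
    frames_missing: tuple[int, ...]
    mean_diameter_px: float
    mm_per_px: float
    nominal_diameter_mm: float = SPHERE_DIAMETER_MM
    diameter_error_mm: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"frame": self.frames_used, "diameter_px": self.diameter_px})
        summary = pd.DataFrame(
            {"frame": ["mean"], "diameter_px": [self.mean_diameter_px]}
        )
        return pd.concat([df, summary], ignore_index=True)

    def save_csv(self, path: "str | Path") -> None:
        self.to_frame().to_csv(path, index=False)


def estimate_sphere_diameter(volume: PseudoVolume) -> tuple[list[float], list[int], list[int]]:
    """Per-frame area-equivalent diameter of the reference-sphere label.

    Returns (diameters_px, frames_used, frames_missing); frames lacking
    the label are skipped and flagged. Raises
    :class:`CalibrationError` when the label is absent everywhere.
    """
    if volume.content_kind != "labelmask":
        raise ValidationError("estimate_sphere_diameter expects a labelmask volume")
    value = LABEL_SCHEME[LandmarkLabel.REFERENCE_SPHERE]
    diameters: list[float] = []
    used: list[int] = []
    missing: list[int] = []
    for f in range(volume.n_frames):
        area = int(np.count_nonzero(volume.voxels[f] == value))
        if area == 0:
            missing.append(f)
            continue
        diameters.append(2.0 * math.sqrt(area / math.pi))
        used.append(f)
    if not diameters:
        raise CalibrationError("reference-sphere label absent in every frame")
    return diameters, used, missing


def mm_per_pixel(mean_diameter_px: float, nominal_diameter_mm: float = SPHERE_DIAMETER_MM) -> float:
    """Isotropic scale (mm/px) from the mean sphere diameter in pixels."""
    if not (mean_diameter_px > 0):
        raise ValidationError(f"mean_diameter_px must be > 0, got {mean_diameter_px}")
    return nominal_diameter_mm / mean_diameter_px


def calibrate(
    volume: PseudoVolume,
    external_mm_per_px: float | None = None,
) -> CalibrationResult:
    """Full calibration of a label volume containing the reference sphere.

    When an external scale is supplied (e.g. the device's nominal pixel
    pitch), the absolute error between the estimated physical sphere
    diameter and its nominal 25 mm is reported as ``diameter_error_mm``.
    """
    diameters, used, missing = estimate_sphere_diameter(volume)
    mean_d = float(np.mean(diameters))
    scale = mm_per_pixel(mean_d)
    error = None
    if external_mm_per_px is not None:
        error = abs(mean_d * external_mm_per_px - SPHERE_DIAMETER_MM)
    return CalibrationResult(
        diameter_px=tuple(diameters),
        frames_used=tuple(used),
        frames_missing=tuple(missing),
        mean_diameter_px=mean_d,
        mm_per_px=scale,
        diameter_error_mm=error,
    )
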