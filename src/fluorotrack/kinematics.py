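"""Arm abduction angle from tracked landmarks.

The abduction angle of a frame is the angle between the image-vertical
direction (gravity is assumed aligned with image columns; y increases
downward) and the line from the glenohumeral joint centre to the
humeral-shaft axis point. An unsigned-magnitude convention is used:
lateral displacement of the shaft relative to the joint centre gives a
positive angle for both sides, with left shoulders mirrored in x. No
smoothing or interpolation is applied — frames where either landmark
failed are flagged invalid, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .labels import LandmarkLabel
from .landmarks import LandmarkSet

__all__ = ["KinematicSeries", "abduction_angle", "kinematic_series", "angle_error", "AngleErrorSummary"]


def abduction_angle(
    gh: tuple[float, float],
    shaft: tuple[float, float],
    side: str = "right",
) -> float:
    """Abduction angle (degrees, unsigned magnitude) for one frame.

    ``gh`` and ``shaft`` are pixel-space (x, y) points; ``side`` selects
    the mirroring that makes lateral displacement positive for left
    shoulders too. 0° means the shaft hangs directly inferior to the
    joint centre; the angle is invariant to uniform scaling about gh.
    """
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    dx = shaft[0] - gh[0]
    dy = shaft[1] - gh[1]
    if dx == 0 and dy == 0:
        raise ValidationError("abduction_angle: joint centre and shaft point coincide")
    if side == "left":
        dx = -dx
    return math.degrees(math.atan2(abs(dx), dy))


@dataclass
class KinematicSeries:
    """Per-frame abduction angles with validity flags.

    ``angles_deg`` is NaN where ``valid`` is False (a required landmark
    failed in that frame).
    """

    angles_deg: np.ndarray
    valid: np.ndarray
    timestamps: np.ndarray
    pulse_rate_hz: float
    side: str

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if not (len(self.angles_deg) == len(self.valid) == len(self.timestamps)):
            raise ValidationError("KinematicSeries arrays must share one length")
        finite = self.angles_deg[self.valid]
        if finite.size and np.nanmax(np.abs(finite)) > 180.0:
            raise ValidationError("abduction angles must lie within ±180°")

    def __len__(self) -> int:
        return len(self.angles_deg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "timestamp": self.timestamps,
                "angle_deg": self.angles_deg,
                "valid": self.valid.astype(int),
            }
        )

    def save_csv(self, path: "str | Path") -> None:
        self.to_frame().to_csv(path, index=False)


def kinematic_series(sets: Sequence[LandmarkSet]) -> KinematicSeries:
    """Abduction-angle time series over a sequence of landmark sets.

    A frame is valid only when both the glenohumeral centre and the
    humeral shaft point are present (neither reported as a failure).
    """
    angles = np.full(len(sets), np.nan)
    valid = np.zeros(len(sets), dtype=bool)
    ts = np.array([s.meta.timestamp for s in sets], dtype=float)
    for i, s in enumerate(sets):
        gh = s.get(LandmarkLabel.GLENOHUMERAL_CENTRE)
        shaft = s.get(LandmarkLabel.HUMERAL_SHAFT)
        if gh is None or shaft is None:
            continue
        angles[i] = abduction_angle(gh.position, shaft.position, s.meta.side)
        valid[i] = True
    pulse = sets[0].meta.pulse_rate_hz if sets else 10.0
    side = sets[0].meta.side if sets else "right"
    return KinematicSeries(angles, valid, ts, pulse, side)


@dataclass(frozen=True)
class AngleErrorSummary:
    """Frame-wise comparison of two abduction-angle series."""

    signed_deg: np.ndarray  # a - b, NaN where excluded
    absolute_deg: np.ndarray
    mean_signed: float
    sd_signed: float
    mean_absolute: float
    sd_absolute: float
    n_compared: int
    n_excluded: int


def angle_error(a: KinematicSeries, b: KinematicSeries) -> AngleErrorSummary:
    """Signed (a − b) and absolute per-frame angle differences.

    Frames invalid in either series are excluded and counted; means and
    sample standard deviations are over the remaining frames.
    """
    if len(a) != len(b):
        raise ValidationError(f"series lengths differ: {len(a)} vs {len(b)}")
    both = a.valid & b.valid
    signed = np.where(both, a.angles_deg - b.angles_deg, np.nan)
    absolute = np.abs(signed)
    vals = signed[both]
    n = int(both.sum())
    return AngleErrorSummary(
        signed_deg=signed,
        absolute_deg=absolute,
        mean_signed=float(np.mean(vals)) if n else float("nan"),
        sd_signed=float(np.std(vals, ddof=1)) if n > 1 else 0.0 if n else float("nan"),
        mean_absolute=float(np.mean(np.abs(vals))) if n else float("nan"),
        sd_absolute=float(np.std(np.abs(vals), ddof=1)) if n > 1 else 0.0 if n else float("nan"),
        n_compared=n,
        n_excluded=len(a) - n,
    )
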