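"""Landmark ⇄ label-mask codec.

Point localisation is recast as semantic segmentation by rasterising a
filled *label disc* at each landmark position: radius 8 px for the three
point landmarks (glenoid edges, acromion), and the fitted-circle radius
for the humeral head, humeral shaft and calibration sphere. Decoding
post-processes a predicted label volume by keeping, per label, only the
largest connected component, then takes each label's per-frame centre of
mass as the landmark position; labels absent from a frame are reported
as detection failures, never imputed.

A pixel belongs to a disc iff the Euclidean distance from its centre
coordinate to the landmark position is ≤ the radius (boundary
inclusive); a radius-8 disc at an integer centre covers exactly 197
pixels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from ._errors import ValidationError
from .labels import (
    CIRCLE_LABELS,
    INT_TO_LABEL,
    LABEL_COLOURS,
    LABEL_SCHEME,
    OVERLAP_PRECEDENCE,
    LandmarkLabel,
)
from .landmarks import Landmark, LandmarkSet, default_radius
from .volume import PseudoVolume

__all__ = [
    "LabelMask",
    "landmarks_to_mask",
    "largest_component_filter",
    "mask_to_landmarks",
    "encode_sequence",
]

log = logging.getLogger(__name__)

_STRUCT_3D = np.ones((3, 3, 3), dtype=np.uint8)  # 26-connectivity
_STRUCT_2D = np.ones((3, 3), dtype=np.uint8)  # 8-connectivity


@dataclass
class LabelMask:
    """A 2D integer label image (0 = background, 1..6 landmark discs)."""

    pixels: np.ndarray
    label_scheme: dict[LandmarkLabel, int] = field(default_factory=lambda: dict(LABEL_SCHEME))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(f"LabelMask must be 2D, got shape {self.pixels.shape}")
        vals = np.unique(self.pixels)
        if vals.size and (vals.min() < 0 or vals.max() > 6):
            raise ValidationError(f"label values must lie in 0..6, found {vals}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _paint_disc(
    mask: np.ndarray, x: float, y: float, radius: float, value: int, label: LandmarkLabel
) -> None:
    """Paint a filled disc into ``mask``, clipping at the image bounds."""
    h, w = mask.shape
    x0 = max(math.ceil(x - radius), 0)
    x1 = min(math.floor(x + radius), w - 1)
    y0 = max(math.ceil(y - radius), 0)
    y1 = min(math.floor(y + radius), h - 1)
    if x0 > x1 or y0 > y1:
        log.warning("disc for %s at (%.2f, %.2f) lies fully outside the image", label.value, x, y)
        return
    if x - radius < -0.5 or x + radius > w - 0.5 or y - radius < -0.5 or y + radius > h - 0.5:
        log.warning("disc for %s at (%.2f, %.2f) clipped at image bounds", label.value, x, y)
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = (xx - x) ** 2 + (yy - y) ** 2 <= radius * radius
    region = mask[y0 : y1 + 1, x0 : x1 + 1]
    if np.any(region[inside] != 0):
        log.warning("disc for %s overlaps a previously painted label", label.value)
    region[inside] = value


def landmarks_to_mask(
    lm_set: LandmarkSet,
    shape: tuple[int, int],
    shaft_fallback_radius: float = 8.0,
) -> LabelMask:
    """Rasterise a frame's landmarks as a labelled disc mask.

    Discs are painted in increasing overlap precedence so that on a
    contested pixel the higher-precedence label wins (sphere > humeral
    head > shaft > acromion > glenoid superior > glenoid inferior).
    Labels recorded as failures are omitted and stay background.
    """
    mask = np.zeros(shape, dtype=np.uint8)
    by_label = {lm.label: lm for lm in lm_set.landmarks}
    for label in OVERLAP_PRECEDENCE:
        lm = by_label.get(label)
        if lm is None:
            continue
        radius = default_radius(label, lm.radius_px, fallback=shaft_fallback_radius)
        _paint_disc(mask, lm.x, lm.y, radius, LABEL_SCHEME[label], label)
    return LabelMask(mask)


def encode_sequence(
    sets: Sequence[LandmarkSet],
    shape: tuple[int, int],
    shaft_fallback_radius: float = 8.0,
) -> PseudoVolume:
    """Rasterise a whole sequence into a labelmask pseudo-volume."""
    frames = [
        (landmarks_to_mask(s, shape, shaft_fallback_radius).pixels, s.meta) for s in sets
    ]
    from .volume import stack_frames

    return stack_frames(frames, content_kind="labelmask")


def largest_component_filter(volume: PseudoVolume, mode: str = "3d") -> PseudoVolume:
    """Keep, per label, only the largest connected component.

    ``mode="3d"`` (default) labels components across the stacked frames
    with 26-connectivity, exploiting the temporal continuity of the
    landmarks; ``mode="2d"`` filters each frame independently with
    8-connectivity. Ties in component size are broken by the component
    whose seed voxel comes first in (frame, y, x) order. Idempotent, and
    the labelled voxel count never increases.
    """
    if volume.content_kind != "labelmask":
        raise ValidationError("largest_component_filter expects a labelmask volume")
    if mode not in ("3d", "2d"):
        raise ValidationError(f"mode must be '3d' or '2d', got {mode!r}")
    arr = volume.voxels
    out = np.zeros_like(arr)
    for value in np.unique(arr):
        if value == 0:
            continue
        binary = arr == value
        if mode == "3d":
            out[_largest_component(binary, _STRUCT_3D)] = value
        else:
            for f in range(arr.shape[0]):
                if binary[f].any():
                    out[f][_largest_component(binary[f], _STRUCT_2D)] = value
    return PseudoVolume(out, list(volume.metas), "labelmask")


def _largest_component(binary: np.ndarray, structure: np.ndarray) -> np.ndarray:
    labelled, n = ndimage.label(binary, structure=structure)
    if n <= 1:
        return binary
    sizes = np.bincount(labelled.ravel())[1:]
    ties = np.flatnonzero(sizes == sizes.max()) + 1
    if ties.size == 1:
        keep = int(ties[0])
    else:
        # tie on size: keep the component whose seed voxel comes first in
        # (frame, y, x) raster order
        flat = labelled.ravel()
        first = flat[np.isin(flat, ties)][0]
        keep = int(first)
    return labelled == keep


def mask_to_landmarks(
    volume: PseudoVolume,
    metas: "Sequence[FrameMeta] | None" = None,
) -> list[LandmarkSet]:
    """Extract landmark coordinates from a (filtered) label volume.

    Per frame and label, the position is the unweighted centroid of the
    label's pixels; circle-bearing labels additionally recover an
    area-equivalent radius sqrt(area/π). A label with no pixels in a
    frame is recorded as a detection failure for that frame.
    """
    if volume.content_kind != "labelmask":
        raise ValidationError("mask_to_landmarks expects a labelmask volume")
    metas = list(metas) if metas is not None else list(volume.metas)
    if len(metas) != volume.n_frames:
        raise ValidationError(f"{len(metas)} metas for {volume.n_frames} frames")
    sets = []
    for f in range(volume.n_frames):
        frame = volume.voxels[f]
        landmarks = []
        failures = []
        for value in sorted(INT_TO_LABEL):
            label = INT_TO_LABEL[value]
            ys, xs = np.nonzero(frame == value)
            if ys.size == 0:
                failures.append(label)
                continue
            pos = (float(xs.mean()), float(ys.mean()))
            radius = math.sqrt(ys.size / math.pi) if label in CIRCLE_LABELS else None
            landmarks.append(Landmark(label, pos, radius))
        sets.append(LandmarkSet(metas[f], tuple(landmarks), frozenset(failures)))
    return sets


# ---------------------------------------------------------------------------
# PNG QC output
# ---------------------------------------------------------------------------


def save_mask_png(mask: LabelMask, path: "str | Path") -> None:
    """Write a label mask as an RGB PNG using the QC palette."""
    import imageio.v3 as iio

    rgb = np.zeros((*mask.shape, 3), dtype=np.uint8)
    for value, colour in LABEL_COLOURS.items():
        rgb[mask.pixels == value] = colour
    iio.imwrite(Path(path), rgb)
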