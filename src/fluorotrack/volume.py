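"""Pseudo-3D volumes: timestamp-ordered stacks of frames or masks.

A fluoroscopic acquisition is a time series of 2D frames; stacking them
along a leading "frame" axis yields a pseudo-3D volume whose third
dimension is acquisition time. A 3D segmenter run on such a volume sees
the frames before and after the current one, which stabilises
predictions on individually blurred frames.

Also provides the dataset-export adapter writing the imagesTr/labelsTr
layout an external 3D segmentation framework consumes, with a manifest
that keeps all sequences of one shoulder together so folds can be
assigned at shoulder level (a network must never be validated on frames
of a shoulder it trained on).
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from ._errors import ValidationError
from .labels import LABEL_SCHEME
from .landmarks import FrameMeta

__all__ = ["PseudoVolume", "stack_frames", "unstack", "export_training_dataset"]


@dataclass
class PseudoVolume:
    """A (frame, y, x) array with per-slice acquisition metadata.

    ``content_kind`` is ``"image"`` for grayscale frames and
    ``"labelmask"`` for integer label volumes.
    """

    voxels: np.ndarray
    metas: list[FrameMeta]
    content_kind: str = "image"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(f"voxels must be 3D (frame, y, x), got shape {self.voxels.shape}")
        if len(self.metas) != self.voxels.shape[0]:
            raise ValidationError(
                f"{len(self.metas)} metas for {self.voxels.shape[0]} slices"
            )
        if self.content_kind not in ("image", "labelmask"):
            raise ValidationError(f"content_kind must be image|labelmask, got {self.content_kind!r}")
        keys = [m.sort_key for m in self.metas]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValidationError(
                "slices must be strictly ordered by (timestamp, source name, frame index)"
            )
        if self.content_kind == "labelmask":
            vals = np.unique(self.voxels)
            if vals.size and (vals.min() < 0 or vals.max() > 6):
                raise ValidationError(f"label values must lie in 0..6, found {vals}")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]  # type: ignore[return-value]


def stack_frames(
    frames: Sequence[tuple[np.ndarray, FrameMeta]],
    content_kind: str = "image",
) -> PseudoVolume:
    """Stack per-frame arrays into a timestamp-ordered pseudo-3D volume.

    Frames are sorted by (timestamp, source file name); equal timestamps
    are broken by name, stably.
    """
    if not frames:
        raise ValidationError("stack_frames: need at least one frame")
    shapes = {np.asarray(img).shape for img, _ in frames}
    if len(shapes) > 1:
        raise ValidationError(f"heterogeneous frame shapes: {sorted(shapes)}")
    order = sorted(range(len(frames)), key=lambda i: frames[i][1].sort_key)
    voxels = np.stack([np.asarray(frames[i][0]) for i in order], axis=0)
    metas = [frames[i][1] for i in order]
    return PseudoVolume(voxels, metas, content_kind)


def unstack(volume: PseudoVolume) -> list[tuple[np.ndarray, FrameMeta]]:
    """Split a pseudo-volume back into (frame, meta) pairs, in slice order."""
    return [(volume.voxels[i], volume.metas[i]) for i in range(volume.n_frames)]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _affine(meta: FrameMeta) -> np.ndarray:
    # frame axis carries unit spacing (time has no physical length);
    # in-plane spacing is the pixel pitch in mm
    sx, sy = meta.pixel_size_mm
    return np.diag([1.0, sy, sx, 1.0])


def save_nifti(volume: PseudoVolume, path: "str | Path") -> None:
    """Write a pseudo-volume as NIfTI: uint8 labels, float32 images."""
    dtype = np.uint8 if volume.content_kind == "labelmask" else np.float32
    data = np.ascontiguousarray(volume.voxels.astype(dtype))
    img = nib.Nifti1Image(data, _affine(volume.metas[0]))
    img.header.set_data_dtype(dtype)
    nib.save(img, str(path))


def load_nifti(
    path: "str | Path",
    content_kind: str,
    metas: "list[FrameMeta] | None" = None,
    pulse_rate_hz: float = 10.0,
    side: str = "right",
) -> PseudoVolume:
    """Read a NIfTI pseudo-volume; metas are rebuilt when not supplied."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if content_kind == "labelmask":
        data = data.astype(np.uint8)
    if metas is None:
        zooms = img.header.get_zooms()
        px = (float(zooms[2]), float(zooms[1])) if len(zooms) >= 3 else (0.35, 0.35)
        metas = [
            FrameMeta(i, pulse_rate_hz=pulse_rate_hz, side=side, pixel_size_mm=px)
            for i in range(data.shape[0])
        ]
    return PseudoVolume(data, metas, content_kind)


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------


def export_training_dataset(
    cases: Sequence[tuple[PseudoVolume, PseudoVolume]],
    out_dir: "str | Path",
    shoulder_ids: "Sequence[str] | None" = None,
    dataset_name: str = "ShoulderFluoroLandmarks",
    overwrite: bool = False,
) -> dict:
    """Export (image, labelmask) cases in the external trainer's layout.

    Writes ``imagesTr/<case>_0000.nii.gz``, ``labelsTr/<case>.nii.gz``
    and a ``dataset.json`` describing the six-label scheme. The returned
    (and written) manifest maps each shoulder id to all of its case
    names, supporting shoulder-level fold assignment.

    ``shoulder_ids`` gives, per case, the shoulder the sequence belongs
    to (e.g. ``"subject03_left"``); defaults to one shoulder per case.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise ValidationError(f"{out}: exists and is not empty (pass overwrite=True)")
        shutil.rmtree(out)
    (out / "imagesTr").mkdir(parents=True, exist_ok=True)
    (out / "labelsTr").mkdir(parents=True, exist_ok=True)

    if shoulder_ids is None:
        shoulder_ids = [f"shoulder{i:03d}" for i in range(len(cases))]
    if len(shoulder_ids) != len(cases):
        raise ValidationError("shoulder_ids must have one entry per case")

    shoulder_to_cases: dict[str, list[str]] = {}
    for i, (img_vol, lab_vol) in enumerate(cases):
        if img_vol.voxels.shape != lab_vol.voxels.shape:
            raise ValidationError(
                f"case {i}: image shape {img_vol.voxels.shape} != "
                f"label shape {lab_vol.voxels.shape}"
            )
        case = f"case{i:03d}"
        save_nifti(img_vol, out / "imagesTr" / f"{case}_0000.nii.gz")
        save_nifti(lab_vol, out / "labelsTr" / f"{case}.nii.gz")
        shoulder_to_cases.setdefault(str(shoulder_ids[i]), []).append(case)

    description = {
        "name": dataset_name,
        "channel_names": {"0": "fluoroscopy"},
        "labels": {"background": 0, **{k.value: v for k, v in LABEL_SCHEME.items()}},
        "numTraining": len(cases),
        "file_ending": ".nii.gz",
    }
    (out / "dataset.json").write_text(json.dumps(description, indent=1))
    manifest = {
        "cases": [f"case{i:03d}" for i in range(len(cases))],
        "shoulder_to_cases": shoulder_to_cases,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
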