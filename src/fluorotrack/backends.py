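"""Segmentation backends: the prediction contract and a ground-truth oracle.

A backend turns an image pseudo-volume into a label pseudo-volume with
the package's fixed label scheme; everything downstream (component
filtering, centroid extraction, calibration, kinematics, agreement) is
backend-agnostic.

Two backends exist:

* :class:`OracleBackend` — encodes known ground-truth landmarks, after
  passing them through a :class:`CorruptionSpec` that emulates the error
  modes of a real segmentation model: rigid per-disc displacement
  (localisation error), per-(label, frame) dropout (detection failures)
  and uniform disc erosion. With the null spec it is an identity oracle.
* :class:`NNUNetAdapter` — a thin shell around the external nnU-Net
  command-line tools, consuming/producing the NIfTI dataset layout. It
  raises a clear dependency error when the framework is not installed;
  there is never a silent fallback.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np

from ._errors import BackendUnavailableError, ValidationError
from .labels import LandmarkLabel, as_label
from .landmarks import Landmark, LandmarkSet, default_radius
from .maskcodec import encode_sequence
from .volume import PseudoVolume

__all__ = ["CorruptionSpec", "OracleBackend", "NNUNetAdapter", "predict", "oracle_predict", "get_backend"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorruptionSpec:
    """Controlled corruption of ground-truth landmarks before encoding.

    Parameters
    ----------
    jitter_sigma_px : float
        Standard deviation of the isotropic Gaussian displacement applied
        rigidly to each disc (per landmark, per frame). 0 disables.
    dropout : mapping label -> set of frame indices
        Frames in which the given label is erased entirely, producing a
        detection failure downstream.
    erosion_px : float
        Uniform shrinkage of every disc radius. Discs eroded to a
        non-positive radius are dropped (with a warning).
    seed : int
        RNG seed; a fixed seed reproduces the output bit-exactly.
    """

    jitter_sigma_px: float = 0.0
    dropout: Mapping[LandmarkLabel, frozenset[int]] = field(default_factory=dict)
    erosion_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma_px < 0:
            raise ValidationError("jitter_sigma_px must be >= 0")
        if self.erosion_px < 0:
            raise ValidationError("erosion_px must be >= 0")
        norm = {as_label(k): frozenset(int(f) for f in v) for k, v in self.dropout.items()}
        object.__setattr__(self, "dropout", norm)

    @property
    def is_null(self) -> bool:
        return self.jitter_sigma_px == 0 and self.erosion_px == 0 and not any(
            self.dropout.values()
        )


def oracle_predict(
    truth: Sequence[LandmarkSet],
    shape: tuple[int, int],
    spec: "CorruptionSpec | None" = None,
    shaft_fallback_radius: float = 8.0,
) -> PseudoVolume:
    """Encode (optionally corrupted) ground-truth landmarks as a label volume.

    Deterministic under a fixed :class:`CorruptionSpec` seed. Jitter
    displaces whole discs rigidly; a jittered disc falling fully outside
    the image is dropped for that frame with a warning.
    """
    spec = spec or CorruptionSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = shape
    corrupted = []
    for i, s in enumerate(truth):
        landmarks = []
        failures = set(s.failures)
        for lm in sorted(s.landmarks, key=lambda m: m.label.value):
            if i in spec.dropout.get(lm.label, frozenset()):
                failures.add(lm.label)
                continue
            x, y = lm.position
            if spec.jitter_sigma_px > 0:
                dx, dy = rng.normal(0.0, spec.jitter_sigma_px, size=2)
                x, y = x + dx, y + dy
            radius = default_radius(lm.label, lm.radius_px, fallback=shaft_fallback_radius)
            radius -= spec.erosion_px
            if radius <= 0:
                log.warning("disc of %s eroded away in frame %d", lm.label.value, i)
                failures.add(lm.label)
                continue
            if x + radius < -0.5 or x - radius > w - 0.5 or y + radius < -0.5 or y - radius > h - 0.5:
                log.warning("jittered disc of %s left the image in frame %d", lm.label.value, i)
                failures.add(lm.label)
                continue
            landmarks.append(Landmark(lm.label, (x, y), radius))
        corrupted.append(LandmarkSet(s.meta, tuple(landmarks), frozenset(failures)))
    return encode_sequence(corrupted, shape, shaft_fallback_radius)


class Backend(Protocol):
    """Prediction contract: image volume in, label volume out."""

    def predict(self, volume: PseudoVolume) -> PseudoVolume: ...


@dataclass
class OracleBackend:
    """Ground-truth oracle backend for desk-scale end-to-end testing."""

    truth: Sequence[LandmarkSet]
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    shaft_fallback_radius: float = 8.0

    def predict(self, volume: PseudoVolume) -> PseudoVolume:
        if len(self.truth) != volume.n_frames:
            raise ValidationError(
                f"oracle has {len(self.truth)} ground-truth frames for a "
                f"volume of {volume.n_frames}"
            )
        return oracle_predict(
            self.truth, volume.frame_shape, self.corruption, self.shaft_fallback_radius
        )


@dataclass
class NNUNetAdapter:
    """Adapter seam for the external nnU-Net segmentation framework.

    Requires the framework's prediction entry point on PATH; model
    weights are referenced by its usual dataset/configuration naming.
    """

    dataset_id: int = 1
    configuration: str = "3d_fullres"
    executable: str = "nnUNetv2_predict"

    def predict(self, volume: PseudoVolume) -> PseudoVolume:
        if shutil.which(self.executable) is None:
            raise BackendUnavailableError(
                f"nnU-Net backend requires {self.executable!r} on PATH "
                "(install the nnunetv2 package and trained weights), "
                "or use the 'oracle' backend"
            )
        # Shell out through the NIfTI layout. Exercised only when the
        # framework is installed.
        import subprocess
        import tempfile
        from pathlib import Path

        from .volume import load_nifti, save_nifti

        with tempfile.TemporaryDirectory() as td:
            tdp = Path(td)
            (tdp / "in").mkdir()
            (tdp / "out").mkdir()
            save_nifti(volume, tdp / "in" / "case000_0000.nii.gz")
            subprocess.run(
                [
                    self.executable,
                    "-i", str(tdp / "in"),
                    "-o", str(tdp / "out"),
                    "-d", str(self.dataset_id),
                    "-c", self.configuration,
                ],
                check=True,
            )
            return load_nifti(
                tdp / "out" / "case000.nii.gz", "labelmask", metas=list(volume.metas)
            )


def get_backend(name: str, **kwargs) -> Backend:
    """Construct a backend by name: ``oracle`` or ``nnunet-adapter``."""
    if name == "oracle":
        return OracleBackend(**kwargs)
    if name == "nnunet-adapter":
        return NNUNetAdapter(**kwargs)
    raise ValidationError(f"unknown backend {name!r}; expected 'oracle' or 'nnunet-adapter'")


def predict(volume: PseudoVolume, backend: Backend) -> PseudoVolume:
    """Run a configured backend on an image volume."""
    out = backend.predict(volume)
    if out.voxels.shape != volume.voxels.shape:
        raise ValidationError(
            f"backend returned shape {out.voxels.shape} for input {volume.voxels.shape}"
        )
    return out
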