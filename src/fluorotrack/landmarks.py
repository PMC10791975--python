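"""Per-frame landmark annotations: domain types and file formats.

Coordinate convention (shared by every module): 0-based pixel indices,
origin at the top-left pixel centre, x increases rightward (image
columns, lateral–medial), y increases downward (image rows,
superior–inferior). Positions are continuous; an integer coordinate is
the centre of that pixel.

Two on-disk formats are supported:

* a flattened markups dialect — JSON with a top-level ``"markups"`` list
  whose entries carry ``"label"``, ``"position"`` [x, y], optional
  ``"radius_px"`` and ``"frame"`` — a documented subset of the 3D Slicer
  point-list schema, accepted either as one file per sequence or one
  file per frame;
* a coordinates CSV with columns
  ``frame,label,x_px,y_px,x_mm,y_mm,failed,radius_px`` (the trailing
  radius column keeps the write→read round trip lossless).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._errors import ParseError, ValidationError
from .labels import CIRCLE_LABELS, LandmarkLabel, as_label

__all__ = [
    "Landmark",
    "FrameMeta",
    "LandmarkSet",
    "read_markups",
    "write_markups",
    "write_coordinates_csv",
    "read_coordinates_csv",
]


@dataclass(frozen=True)
class Landmark:
    """A single landmark observation in one frame.

    Parameters
    ----------
    label : LandmarkLabel
        Which of the six landmark identities this is.
    position : (float, float)
        Sub-pixel (x, y) position in pixel units.
    radius_px : float, optional
        Best-fit circle radius in pixels. Present for the humeral head
        (glenohumeral centre), humeral shaft and reference sphere;
        absent for the three fixed-radius point landmarks.
    """

    label: LandmarkLabel
    position: tuple[float, float]
    radius_px: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", as_label(self.label))
        x, y = self.position
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValidationError(f"landmark {self.label}: non-finite position {self.position}")
        object.__setattr__(self, "position", (float(x), float(y)))
        if self.radius_px is not None:
            r = float(self.radius_px)
            if not (math.isfinite(r) and r > 0):
                raise ValidationError(f"landmark {self.label}: radius_px must be > 0, got {r}")
            object.__setattr__(self, "radius_px", r)

    @property
    def x(self) -> float:
        return self.position[0]

    @property
    def y(self) -> float:
        return self.position[1]


@dataclass(frozen=True)
class FrameMeta:
    """Acquisition metadata for one fluoroscopic frame.

    ``timestamp`` defaults to ``frame_index / pulse_rate_hz`` so that
    ordering stays total even when the source carries no timestamps.
    """

    frame_index: int
    pulse_rate_hz: float = 10.0
    timestamp: float | None = None
    side: str = "right"
    pixel_size_mm: tuple[float, float] = (0.35, 0.35)
    source_name: str | None = None

    def __post_init__(self) -> None:
        if self.pulse_rate_hz <= 0:
            raise ValidationError(f"pulse_rate_hz must be > 0, got {self.pulse_rate_hz}")
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        sx, sy = self.pixel_size_mm
        if sx <= 0 or sy <= 0:
            raise ValidationError(f"pixel_size_mm must be positive, got {self.pixel_size_mm}")
        if self.timestamp is None:
            object.__setattr__(self, "timestamp", self.frame_index / self.pulse_rate_hz)

    @property
    def sort_key(self) -> tuple[float, str, int]:
        """(timestamp, source file name, frame index) — ties broken stably."""
        return (float(self.timestamp), self.source_name or "", self.frame_index)


@dataclass(frozen=True)
class LandmarkSet:
    """All landmark observations (and reported failures) of one frame.

    A label appears either in ``landmarks`` or in ``failures``, never in
    both; duplicates within ``landmarks`` are rejected.
    """

    meta: FrameMeta
    landmarks: tuple[Landmark, ...] = ()
    failures: frozenset[LandmarkLabel] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "landmarks", tuple(self.landmarks))
        object.__setattr__(self, "failures", frozenset(as_label(f) for f in self.failures))
        seen: set[LandmarkLabel] = set()
        for lm in self.landmarks:
            if lm.label in seen:
                raise ValidationError(
                    f"frame {self.meta.frame_index}: duplicate landmark {lm.label.value}"
                )
            seen.add(lm.label)
        clash = seen & self.failures
        if clash:
            raise ValidationError(
                f"frame {self.meta.frame_index}: labels both present and failed: "
                + ", ".join(sorted(c.value for c in clash))
            )

    def get(self, label: "str | LandmarkLabel") -> Landmark | None:
        label = as_label(label)
        for lm in self.landmarks:
            if lm.label == label:
                return lm
        return None

    def __contains__(self, label: object) -> bool:
        return any(lm.label == as_label(label) for lm in self.landmarks)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Markups dialect (JSON)
# ---------------------------------------------------------------------------


def _parse_one_markup(rec: dict, idx: int, path: Path) -> tuple[int, Landmark]:
    try:
        label = as_label(rec["label"])
        pos = rec["position"]
        if not (isinstance(pos, (list, tuple)) and len(pos) == 2):
            raise ValueError(f"position must be [x, y], got {pos!r}")
        radius = rec.get("radius_px")
        frame = int(rec.get("frame", 0))
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: markups[{idx}]: {exc}") from exc
    try:
        lm = Landmark(label, (float(pos[0]), float(pos[1])), radius)
    except (TypeError, ValueError, ValidationError) as exc:
        raise ParseError(f"{path}: markups[{idx}] ({label.value}): {exc}") from exc
    return frame, lm


def _read_markups_file(path: Path, frame_offset: int = 0) -> list[LandmarkSet]:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "markups" not in doc:
        raise ParseError(f"{path}: expected an object with a top-level 'markups' list")

    meta_doc = doc.get("meta", {})
    pulse = float(meta_doc.get("pulse_rate_hz", 10.0))
    side = meta_doc.get("side", "right")
    px = meta_doc.get("pixel_size_mm", [0.35, 0.35])
    pixel_size = (float(px[0]), float(px[1])) if isinstance(px, (list, tuple)) else (float(px), float(px))

    by_frame: dict[int, list[Landmark]] = {}
    for idx, rec in enumerate(doc["markups"]):
        frame, lm = _parse_one_markup(rec, idx, path)
        by_frame.setdefault(frame + frame_offset, []).append(lm)

    frame_info: dict[int, dict] = {}
    for rec in doc.get("frames", []):
        frame_info[int(rec["frame"]) + frame_offset] = rec

    all_frames = sorted(set(by_frame) | set(frame_info))
    sets = []
    for f in all_frames:
        info = frame_info.get(f, {})
        ts = info.get("timestamp")
        meta = FrameMeta(
            frame_index=f,
            pulse_rate_hz=pulse,
            timestamp=None if ts is None else float(ts),
            side=side,
            pixel_size_mm=pixel_size,
            source_name=path.name,
        )
        failures = frozenset(as_label(x) for x in info.get("failures", []))
        sets.append(LandmarkSet(meta, tuple(by_frame.get(f, [])), failures))
    return sets


def read_markups(path: "str | Path | Sequence[str | Path]") -> list[LandmarkSet]:
    """Read landmark annotations from the markups dialect.

    ``path`` may be a single per-sequence JSON file, a directory of
    one-file-per-frame JSONs, or an explicit list of files. Frames are
    returned ordered by (timestamp, file name).
    """
    if isinstance(path, (str, Path)):
        p = Path(path)
        if p.is_dir():
            files = sorted(q for q in p.iterdir() if q.suffix == ".json")
            if not files:
                raise ParseError(f"{p}: directory contains no .json markups files")
        else:
            if not p.exists():
                raise ParseError(f"{p}: no such file")
            files = [p]
    else:
        files = [Path(q) for q in path]

    sets: list[LandmarkSet] = []
    if len(files) == 1:
        sets = _read_markups_file(files[0])
    else:
        # one file per frame: file order supplies the frame index when the
        # file does not state one
        for i, f in enumerate(sorted(files)):
            frame_sets = _read_markups_file(f, frame_offset=0)
            for s in frame_sets:
                if len(frame_sets) == 1 and s.meta.frame_index == 0:
                    meta = replace(s.meta, frame_index=i, timestamp=None)
                    s = LandmarkSet(meta, s.landmarks, s.failures)
                sets.append(s)
    sets.sort(key=lambda s: s.meta.sort_key)
    return sets


def write_markups(sets: Iterable[LandmarkSet], path: "str | Path") -> None:
    """Write a sequence of LandmarkSets as one per-sequence markups file."""
    sets = list(sets)
    markups = []
    frames = []
    for s in sets:
        for lm in s.landmarks:
            rec: dict = {
                "label": lm.label.value,
                "position": [lm.x, lm.y],
                "frame": s.meta.frame_index,
            }
            if lm.radius_px is not None:
                rec["radius_px"] = lm.radius_px
            markups.append(rec)
        frames.append(
            {
                "frame": s.meta.frame_index,
                "timestamp": s.meta.timestamp,
                "failures": sorted(f.value for f in s.failures),
            }
        )
    meta = {}
    if sets:
        m = sets[0].meta
        meta = {
            "pulse_rate_hz": m.pulse_rate_hz,
            "side": m.side,
            "pixel_size_mm": list(m.pixel_size_mm),
        }
    doc = {"meta": meta, "frames": frames, "markups": markups}
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# Coordinates CSV
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["frame", "label", "x_px", "y_px", "x_mm", "y_mm", "failed", "radius_px"]


def write_coordinates_csv(
    sets: Sequence[LandmarkSet],
    path: "str | Path",
    mm_per_px: float | None = None,
) -> None:
    """Write extracted coordinates as CSV, one row per (frame, label).

    Millimetre columns are filled when a calibration scale is supplied
    and left empty otherwise. Failure rows carry the flag and empty
    coordinates.
    """
    if not sets:
        raise ValidationError("write_coordinates_csv: empty sequence of LandmarkSets")
    rows = []
    for s in sets:
        for lm in s.landmarks:
            rows.append(
                {
                    "frame": s.meta.frame_index,
                    "label": lm.label.value,
                    "x_px": lm.x,
                    "y_px": lm.y,
                    "x_mm": lm.x * mm_per_px if mm_per_px else None,
                    "y_mm": lm.y * mm_per_px if mm_per_px else None,
                    "failed": 0,
                    "radius_px": lm.radius_px,
                }
            )
        for lab in sorted(f.value for f in s.failures):
            rows.append(
                {
                    "frame": s.meta.frame_index,
                    "label": lab,
                    "x_px": None,
                    "y_px": None,
                    "x_mm": None,
                    "y_mm": None,
                    "failed": 1,
                    "radius_px": None,
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_coordinates_csv(
    path: "str | Path",
    pulse_rate_hz: float = 10.0,
    side: str = "right",
    pixel_size_mm: tuple[float, float] = (0.35, 0.35),
) -> list[LandmarkSet]:
    """Read a coordinates CSV back into LandmarkSets.

    Acquisition metadata is not stored in the CSV; the caller supplies it
    (defaults match the nominal acquisition settings).
    """
    df = pd.read_csv(Path(path))
    missing = [c for c in _CSV_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    sets = []
    for frame, grp in df.groupby("frame", sort=True):
        landmarks = []
        failures = []
        for _, row in grp.iterrows():
            label = as_label(str(row["label"]))
            if int(row["failed"]):
                failures.append(label)
            else:
                radius = row.get("radius_px")
                radius = None if radius is None or pd.isna(radius) else float(radius)
                landmarks.append(Landmark(label, (float(row["x_px"]), float(row["y_px"])), radius))
        meta = FrameMeta(
            frame_index=int(frame),
            pulse_rate_hz=pulse_rate_hz,
            side=side,
            pixel_size_mm=pixel_size_mm,
        )
        sets.append(LandmarkSet(meta, tuple(landmarks), frozenset(failures)))
    return sets


def default_radius(label: LandmarkLabel, radius_px: float | None, fallback: float = 8.0) -> float:
    """Disc radius used when rasterising a landmark.

    Circle-bearing landmarks use their fitted radius when present and
    fall back to ``fallback`` (8 px, matching the fixed-radius discs)
    when the annotation carries none.
    """
    if radius_px is not None:
        return radius_px
    if label in CIRCLE_LABELS:
        return fallback
    return 8.0
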