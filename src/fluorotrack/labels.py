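"""Landmark identities and the fixed integer label scheme.

Five anatomical landmarks of the shoulder plus the radio-opaque
calibration sphere. Masks encode each landmark as a filled disc carrying
the label integer below; 0 is background.
"""

from __future__ import annotations

import enum


class LandmarkLabel(str, enum.Enum):
    """The five anatomical landmarks and the calibration sphere."""

    GLENOHUMERAL_CENTRE = "glenohumeral_centre"
    GLENOID_SUPERIOR = "glenoid_superior"
    GLENOID_INFERIOR = "glenoid_inferior"
    ACROMION_LATERAL = "acromion_lateral"
    HUMERAL_SHAFT = "humeral_shaft"
    REFERENCE_SPHERE = "reference_sphere"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Integer label carried by each landmark's disc in a label mask.
LABEL_SCHEME: dict[LandmarkLabel, int] = {
    LandmarkLabel.GLENOHUMERAL_CENTRE: 1,
    LandmarkLabel.GLENOID_SUPERIOR: 2,
    LandmarkLabel.GLENOID_INFERIOR: 3,
    LandmarkLabel.ACROMION_LATERAL: 4,
    LandmarkLabel.HUMERAL_SHAFT: 5,
    LandmarkLabel.REFERENCE_SPHERE: 6,
}

INT_TO_LABEL: dict[int, LandmarkLabel] = {v: k for k, v in LABEL_SCHEME.items()}

#: Landmarks rasterised with a fixed 8 px disc radius (point landmarks on
#: bony edges; no fitted circle exists for them).
FIXED_RADIUS_PX = 8.0
FIXED_RADIUS_LABELS = frozenset(
    {
        LandmarkLabel.GLENOID_SUPERIOR,
        LandmarkLabel.GLENOID_INFERIOR,
        LandmarkLabel.ACROMION_LATERAL,
    }
)

#: Landmarks whose disc radius comes from a best-fit circle (humeral head,
#: shaft, calibration sphere).
CIRCLE_LABELS = frozenset(
    {
        LandmarkLabel.GLENOHUMERAL_CENTRE,
        LandmarkLabel.HUMERAL_SHAFT,
        LandmarkLabel.REFERENCE_SPHERE,
    }
)

#: Overlap precedence when rasterising discs: higher wins a contested pixel.
#: Larger structures are least harmed by losing a boundary pixel.
OVERLAP_PRECEDENCE: tuple[LandmarkLabel, ...] = (
    LandmarkLabel.GLENOID_INFERIOR,
    LandmarkLabel.GLENOID_SUPERIOR,
    LandmarkLabel.ACROMION_LATERAL,
    LandmarkLabel.HUMERAL_SHAFT,
    LandmarkLabel.GLENOHUMERAL_CENTRE,
    LandmarkLabel.REFERENCE_SPHERE,
)

#: Display palette for per-frame PNG QC output (RGB), by label integer.
#: Sphere red, humeral head yellow, acromion blue, glenoid superior pink,
#: glenoid inferior white, shaft light blue.
LABEL_COLOURS: dict[int, tuple[int, int, int]] = {
    0: (0, 0, 0),
    1: (255, 255, 0),
    2: (255, 105, 180),
    3: (255, 255, 255),
    4: (0, 0, 255),
    5: (135, 206, 250),
    6: (255, 0, 0),
}

#: Nominal diameter of the in-field calibration sphere, millimetres.
SPHERE_DIAMETER_MM = 25.0


def as_label(value: "str | LandmarkLabel") -> LandmarkLabel:
    """Coerce a string or enum member to :class:`LandmarkLabel`."""
    if isinstance(value, LandmarkLabel):
        return value
    try:
        return LandmarkLabel(value)
    except ValueError as exc:
        known = ", ".join(m.value for m in LandmarkLabel)
        raise ValueError(f"unknown landmark label {value!r}; expected one of: {known}") from exc
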