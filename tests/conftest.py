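import numpy as np
import pytest

from fluorotrack.labels import LandmarkLabel
from fluorotrack.landmarks import FrameMeta, Landmark, LandmarkSet
from fluorotrack.phantom import PhantomConfig, ground_truth


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Downscaled phantom geometry for fast tests (same 0.35 mm/px)."""
    return PhantomConfig(
        image_shape=(300, 300),
        pulse_rate_hz=10.0,
        movement_duration_s=2.0,
        gh_centre_px=(140.0, 100.0),
        humeral_head_radius_mm=15.0,
        shaft_length_mm=40.0,
        shaft_half_width_mm=4.0,
        glenoid_superior_offset_mm=(-18.0, -10.0),
        glenoid_inferior_offset_mm=(-19.0, 10.0),
        acromion_offset_mm=(12.0, -21.0),
        sphere_centre_px=(240.0, 240.0),
        seed=0,
    )


@pytest.fixture(scope="session")
def small_truth(small_config) -> list[LandmarkSet]:
    return ground_truth(small_config)


def make_set(
    positions: dict[LandmarkLabel, tuple[float, float]],
    radii: dict[LandmarkLabel, float] | None = None,
    frame: int = 0,
    failures=(),
    pulse_rate: float = 10.0,
    side: str = "right",
) -> LandmarkSet:
    """Build a LandmarkSet from a {label: position} mapping."""
    radii = radii or {}
    lms = tuple(Landmark(lab, pos, radii.get(lab)) for lab, pos in positions.items())
    meta = FrameMeta(frame, pulse_rate_hz=pulse_rate, side=side)
    return LandmarkSet(meta, lms, frozenset(failures))


#: well-separated static positions on a 300x300 frame, used by several tests
SEPARATED_POSITIONS = {
    LandmarkLabel.GLENOHUMERAL_CENTRE: (60.0, 60.0),
    LandmarkLabel.GLENOID_SUPERIOR: (60.0, 180.0),
    LandmarkLabel.GLENOID_INFERIOR: (180.0, 60.0),
    LandmarkLabel.ACROMION_LATERAL: (180.0, 180.0),
    LandmarkLabel.HUMERAL_SHAFT: (120.0, 250.0),
    LandmarkLabel.REFERENCE_SPHERE: (250.0, 120.0),
}

SEPARATED_RADII = {
    LandmarkLabel.GLENOHUMERAL_CENTRE: 20.0,
    LandmarkLabel.HUMERAL_SHAFT: 8.0,
    LandmarkLabel.REFERENCE_SPHERE: 30.0,
}


def brute_force_disc(cx: float, cy: float, r: float, shape=(1000, 1000)) -> set[tuple[int, int]]:
    """Independent O(n^2) lattice enumeration of a disc's pixel set."""
    pixels = set()
    x0, x1 = int(np.floor(cx - r)) - 1, int(np.ceil(cx + r)) + 1
    y0, y1 = int(np.floor(cy - r)) - 1, int(np.ceil(cy + r)) + 1
    for x in range(max(x0, 0), min(x1, shape[1] - 1) + 1):
        for y in range(max(y0, 0), min(y1, shape[0] - 1) + 1):
            if (x - cx) ** 2 + (y - cy) ** 2 <= r * r:
                pixels.add((x, y))
    return pixels


def random_separated_sets(
    rng: np.random.Generator,
    n_frames: int,
    shape=(200, 200),
    integer_centres: bool = False,
) -> list[LandmarkSet]:
    """Random landmark sets with in-bounds, pairwise non-overlapping discs.

    Positions are drawn independently per frame; disc radii are 8 px for
    every label plus fitted radii for the circle-bearing ones.
    """
    h, w = shape
    sets = []
    radii = {
        LandmarkLabel.GLENOHUMERAL_CENTRE: 14.0,
        LandmarkLabel.HUMERAL_SHAFT: 8.0,
        LandmarkLabel.REFERENCE_SPHERE: 18.0,
    }
    for f in range(n_frames):
        placed: list[tuple[float, float, float]] = []
        positions = {}
        for label in LandmarkLabel:
            r = radii.get(label, 8.0)
            for _ in range(1000):
                x = rng.uniform(r + 1, w - r - 2)
                y = rng.uniform(r + 1, h - r - 2)
                if integer_centres:
                    x, y = float(round(x)), float(round(y))
                if all(np.hypot(x - px, y - py) > r + pr + 2 for px, py, pr in placed):
                    placed.append((x, y, r))
                    positions[label] = (x, y)
                    break
            else:  # pragma: no cover - generation failure
                raise RuntimeError("could not place non-overlapping discs")
        sets.append(make_set(positions, radii, frame=f))
    return sets
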