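"""Canonical landmark layouts of the two homing experiments.

Experiment 1 ("number of landmarks"): 1, 2, or 3 identical landmarks
placed at a fixed distance around the home position - 2 m in the auditory
arena, 6 virtual meters in the VR environment.  The three landmarks form
an equilateral triangle with home at its centroid; the 1- and 2-landmark
conditions use subsets of that triangle.

Experiment 2 ("relocation"): the visual 3-landmark layout, with one
landmark displaced between training and test by 0-6 vm in steps of
1.5 vm, orthogonally away from the line through the other two.
"""

from __future__ import annotations

import math

from .combination import circle_intersections, relocate
from .model_core import LandmarkConfiguration, Point2D

__all__ = [
    "AUDITORY_RADIUS",
    "VISUAL_RADIUS",
    "RELOCATIONS",
    "landmark_radius",
    "exp1_configuration",
    "exp2_base_configuration",
    "exp2_relocated_configuration",
    "stationary_pair_intersections",
]

AUDITORY_RADIUS = 2.0  # meters, sports-hall layout
VISUAL_RADIUS = 6.0  # virtual meters, VR layout

#: Relocation magnitudes of the conflict experiment (virtual meters).
RELOCATIONS = (0.0, 1.5, 3.0, 4.5, 6.0)

#: The relocated landmark sits at the top of the triangle; moving it along
#: +y is orthogonal to (and away from) the other two.
DEVIANT_INDEX = 0

_ANGLES_DEG = (90.0, 210.0, 330.0)


def landmark_radius(geometry: str) -> float:
    try:
        return {"auditory": AUDITORY_RADIUS, "visual": VISUAL_RADIUS}[geometry]
    except KeyError:
        raise ValueError(f"unknown geometry {geometry!r} (use 'auditory' or 'visual')")


def exp1_configuration(
    geometry: str, n_landmarks: int, home: Point2D = Point2D(0.0, 0.0)
) -> LandmarkConfiguration:
    """The 1/2/3-landmark layout at the trained radius for one modality."""
    if not 1 <= n_landmarks <= 3:
        raise ValueError("n_landmarks must be 1, 2, or 3")
    r = landmark_radius(geometry)
    landmarks = tuple(
        Point2D(
            home.x + r * math.cos(math.radians(a)),
            home.y + r * math.sin(math.radians(a)),
        )
        for a in _ANGLES_DEG[:n_landmarks]
    )
    return LandmarkConfiguration(
        home=home,
        training_landmarks=landmarks,
        test_landmarks=landmarks,
        label=f"{geometry}-{n_landmarks}lm",
    )


def exp2_base_configuration(home: Point2D = Point2D(0.0, 0.0)) -> LandmarkConfiguration:
    """Training layout of the relocation experiment (visual, 3 landmarks)."""
    cfg = exp1_configuration("visual", 3, home)
    return LandmarkConfiguration(
        home=cfg.home,
        training_landmarks=cfg.training_landmarks,
        test_landmarks=cfg.test_landmarks,
        label="exp2-base",
    )


def exp2_relocated_configuration(
    relocation: float, home: Point2D = Point2D(0.0, 0.0)
) -> LandmarkConfiguration:
    return relocate(exp2_base_configuration(home), relocation, DEVIANT_INDEX)


def stationary_pair_intersections(
    config: LandmarkConfiguration, deviant_index: int = DEVIANT_INDEX
) -> tuple[Point2D, Point2D]:
    """Ring intersections of the two non-relocated landmarks.

    Returns (near, far): the intersection on the deviant landmark's side
    (which coincides with home for the trained layout) first, its mirror
    second.
    """
    deviant_index = deviant_index % config.n_landmarks
    (c1, r1), (c2, r2) = [(lm, config.home.distance_to(tr)) for i, (lm, tr) in
                          enumerate(zip(config.test_landmarks, config.training_landmarks))
                          if i != deviant_index]
    p, q = circle_intersections(c1, r1, c2, r2)
    deviant = config.test_landmarks[deviant_index]
    if p.distance_to(deviant) <= q.distance_to(deviant):
        return p, q
    return q, p
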