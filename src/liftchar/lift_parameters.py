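"""Geometric lift parameters: asymmetry, heights, displacement, distance.

All quantities are derived from the hands midpoint (taken as the location of
the carried object), the feet midpoint, and the mean foot heading:

* **asymmetry angle** -- signed floor-plane angle from the facing direction
  (normalized sum of the foot headings) to the feet-midpoint -> hands-midpoint
  direction. Counterclockwise seen from above (a twist to the left) is
  positive; the range is (-180, 180] degrees.
* **vertical height** -- Z coordinate of the hands midpoint.
* **vertical displacement** -- height at the end minus height at the start,
  so a floor-to-chest lift is positive.
* **horizontal distance** -- floor-plane distance from the feet midpoint to
  the hands midpoint.

Reference values for the study protocol geometry (shelf heights plus the
hand-to-crate-bottom offset) are exposed as module constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trial_model import LiftWindow, MotionTrial

__all__ = [
    "SHELF_HEIGHTS",
    "HAND_CRATE_OFFSET",
    "REFERENCE_HEIGHTS",
    "REFERENCE_HORIZONTAL",
    "reference_displacement",
    "LiftParameters",
    "DegenerateGeometryError",
    "facing_direction",
    "asymmetry_angle",
    "lift_asymmetry",
    "vertical_height",
    "vertical_displacement",
    "horizontal_distance",
    "estimate_parameters",
]

#: Shelf surface heights of the protocol, meters (the floor is 0).
SHELF_HEIGHTS: dict[str, float] = {
    "floor": 0.0,
    "knee": 0.54,
    "chest": 1.08,
    "head": 1.57,
}

#: Approximate height of the hands above the bottom of the crate, meters.
HAND_CRATE_OFFSET: float = 0.30

#: Nominal hand-midpoint height per vertical level: shelf + hand offset.
REFERENCE_HEIGHTS: dict[str, float] = {
    level: h + HAND_CRATE_OFFSET for level, h in SHELF_HEIGHTS.items()
}

#: Tape-measured horizontal rest distances per level, meters.
REFERENCE_HORIZONTAL: dict[str, float] = {
    "floor": 0.30,
    "knee": 0.50,
    "chest": 0.45,
    "head": 0.45,
}


def reference_displacement(source: str, destination: str) -> float:
    """Nominal vertical displacement of a source->destination lift (m)."""
    return REFERENCE_HEIGHTS[destination] - REFERENCE_HEIGHTS[source]


class DegenerateGeometryError(ValueError):
    """Feet or hand geometry does not define the requested direction."""


@dataclass(frozen=True)
class LiftParameters:
    """All geometric parameters of one lift.

    ``asym_max`` is the endpoint asymmetry angle of larger magnitude (sign
    preserved); ``asym_diff`` is end minus start. ``duration`` is the window
    length in seconds.
    """

    asym_start: float
    asym_end: float
    asym_max: float
    asym_diff: float
    height_start: float
    height_end: float
    vertical_displacement: float
    horiz_start: float
    horiz_end: float
    duration: float


def _feet_midpoint(trial: MotionTrial, frame: int) -> np.ndarray:
    return 0.5 * (trial.foot_pos["left"][frame] + trial.foot_pos["right"][frame])


def _hands_midpoint(trial: MotionTrial, frame: int) -> np.ndarray:
    return 0.5 * (trial.hand_pos["left"][frame] + trial.hand_pos["right"][frame])


def facing_direction(trial: MotionTrial, frame: int) -> np.ndarray:
    """Floor-plane unit vector the participant is facing at ``frame``.

    Computed as the normalized sum of the two foot heading vectors (the
    vector-sum mean of the foot orientations). Exactly opposed feet leave the
    direction undefined.
    """
    total = trial.foot_heading["left"][frame] + trial.foot_heading["right"][frame]
    norm = np.linalg.norm(total)
    if norm < 1e-9:
        raise DegenerateGeometryError(
            f"foot headings at frame {frame} are opposed; facing direction undefined"
        )
    return total / norm


def asymmetry_angle(trial: MotionTrial, frame: int) -> float:
    """Signed twist angle (degrees) of the hands relative to facing.

    The angle from the facing direction to the floor-plane projection of the
    feet-midpoint -> hands-midpoint vector, counterclockwise-positive when
    viewed from above, in (-180, 180].
    """
    facing = facing_direction(trial, frame)
    offset = (_hands_midpoint(trial, frame) - _feet_midpoint(trial, frame))[:2]
    norm = np.linalg.norm(offset)
    if norm < 1e-9:
        raise DegenerateGeometryError(
            f"hands midpoint is above the feet midpoint at frame {frame}; "
            "twist direction undefined"
        )
    cross = facing[0] * offset[1] - facing[1] * offset[0]
    dot = facing[0] * offset[0] + facing[1] * offset[1]
    angle = math.degrees(math.atan2(cross, dot))
    if angle <= -180.0:  # map the branch cut onto +180
        angle += 360.0
    return angle


def lift_asymmetry(trial: MotionTrial, window: LiftWindow) -> tuple[float, float, float, float]:
    """Asymmetry at the lift endpoints: (start, end, largest-magnitude, diff)."""
    asym_start = asymmetry_angle(trial, window.start_frame)
    asym_end = asymmetry_angle(trial, window.last_frame())
    asym_max = asym_start if abs(asym_start) >= abs(asym_end) else asym_end
    return asym_start, asym_end, asym_max, asym_end - asym_start


def vertical_height(trial: MotionTrial, frame: int) -> float:
    """Height of the object (hands midpoint Z) above the floor, meters."""
    return float(_hands_midpoint(trial, frame)[2])


def vertical_displacement(trial: MotionTrial, window: LiftWindow) -> float:
    """Object height at the end of the lift minus height at the start (m)."""
    return vertical_height(trial, window.last_frame()) - vertical_height(
        trial, window.start_frame
    )


def horizontal_distance(trial: MotionTrial, frame: int) -> float:
    """Floor-plane distance from the feet midpoint to the object (m)."""
    offset = (_hands_midpoint(trial, frame) - _feet_midpoint(trial, frame))[:2]
    return float(np.linalg.norm(offset))


def estimate_parameters(trial: MotionTrial, window: LiftWindow) -> LiftParameters:
    """Assemble every lift parameter for a detected or labeled window."""
    asym_start, asym_end, asym_max, asym_diff = lift_asymmetry(trial, window)
    height_start = vertical_height(trial, window.start_frame)
    height_end = vertical_height(trial, window.last_frame())
    return LiftParameters(
        asym_start=asym_start,
        asym_end=asym_end,
        asym_max=asym_max,
        asym_diff=asym_diff,
        height_start=height_start,
        height_end=height_end,
        vertical_displacement=height_end - height_start,
        horiz_start=horizontal_distance(trial, window.start_frame),
        horiz_end=horizontal_distance(trial, window.last_frame()),
        duration=window.duration,
    )
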