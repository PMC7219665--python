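"""The 223-entry feature pool per lift and the published feature sets.

The pool comprises, in fixed registry order:

* 84 joint movements -- end-of-lift angle minus start-of-lift angle for 28
  joints on 3 axes each (degrees);
* 84 magnitudes of those movements;
* 23 segment mean absolute velocities over the window (m/s);
* 23 segment mean absolute accelerations (m/s^2);
* 9 lift parameters: start/end object height, start/end horizontal distance,
  start/end asymmetry angle, vertical displacement, largest-magnitude
  asymmetry, and asymmetry difference.

One derived quantity sits outside the pool: the maximum trunk inclination
over the window (``trunk_inclination_max``), the trunk-vs-vertical posture
feature. :func:`feature_table` includes it alongside the pool so the
published posture feature set can be evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .lift_detection import detect_lift
from .lift_parameters import estimate_parameters
from .trial_model import JOINT_AXES, JOINTS, SEGMENTS, LiftWindow, MotionTrial

__all__ = [
    "FEATURE_NAMES",
    "PARAMETER_FEATURES",
    "TRUNK_INCLINATION_FEATURE",
    "SUBPROBLEMS",
    "FeatureSetSpec",
    "PUBLISHED_EXCLUSIONS",
    "joint_movement",
    "segment_mean_abs_kinematics",
    "trunk_inclination_max",
    "extract_features",
    "published_feature_set",
    "feature_table",
]

PARAMETER_FEATURES: tuple[str, ...] = (
    "height_start", "height_end",
    "horiz_start", "horiz_end",
    "asym_start", "asym_end",
    "vertical_displacement", "asym_max", "asym_diff",
)

#: Ordered names of the full feature pool (exactly 223 entries).
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"d_{j}_{ax}" for j in JOINTS for ax in JOINT_AXES)
    + tuple(f"absd_{j}_{ax}" for j in JOINTS for ax in JOINT_AXES)
    + tuple(f"mav_{seg}" for seg in SEGMENTS)
    + tuple(f"maa_{seg}" for seg in SEGMENTS)
    + PARAMETER_FEATURES
)

TRUNK_INCLINATION_FEATURE = "trunk_inclination_max"

SUBPROBLEMS = ("posture", "asymmetry", "vertical_movement", "weight")


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named feature subset for one classification subproblem."""

    subproblem: str
    features: tuple[str, ...]


_PUBLISHED_SETS: dict[str, tuple[str, ...]] = {
    # trunk-vertical angle + |flexion-extension movements| of knees,
    # shoulders and hips
    "posture": (
        TRUNK_INCLINATION_FEATURE,
        "absd_jLeftKnee_ax3", "absd_jRightKnee_ax3",
        "absd_jLeftShoulder_ax3", "absd_jRightShoulder_ax3",
        "absd_jLeftHip_ax3", "absd_jRightHip_ax3",
    ),
    # twist-angle difference, largest twist angle, and upper-spine movement
    # about the forward axis
    "asymmetry": ("asym_diff", "asym_max", "d_jT9T8_ax1"),
    # object displacement plus hand heights at the endpoints
    "vertical_movement": ("vertical_displacement", "height_start", "height_end"),
    # mean absolute speeds of the hands and head
    "weight": ("mav_LeftHand", "mav_RightHand", "mav_Head"),
}

#: Features removed by hand from automatic selections because they pick up
#: protocol artifacts rather than the quantity being classified (e.g. all
#: light lifts in the protocol were straight chest/floor lifts).
PUBLISHED_EXCLUSIONS: dict[str, tuple[str, ...]] = {
    "weight": ("asym_max", "d_Pelvis_T8_ax2", "horiz_start", "horiz_end"),
    "posture": ("height_start", "height_end"),
    "asymmetry": (),
    "vertical_movement": (),
}


def joint_movement(trial: MotionTrial, window: LiftWindow, joint: str, axis: str) -> float:
    """Joint angle at the end of the lift minus the angle at the start (deg)."""
    if joint not in trial.joint_angle:
        raise KeyError(f"unknown joint {joint!r}")
    if axis not in JOINT_AXES:
        raise KeyError(f"unknown axis {axis!r}; expected one of {JOINT_AXES}")
    series = trial.joint_angle[joint][:, JOINT_AXES.index(axis)]
    return float(series[window.last_frame()] - series[window.start_frame])


def segment_mean_abs_kinematics(
    trial: MotionTrial, window: LiftWindow, segment: str
) -> tuple[float, float]:
    """Mean Euclidean speed and acceleration magnitude over the window."""
    if segment not in trial.segment_vel:
        raise KeyError(f"unknown segment {segment!r}")
    sl = slice(window.start_frame, window.end_frame)
    speed = np.linalg.norm(trial.segment_vel[segment][sl], axis=1)
    accel = np.linalg.norm(trial.segment_acc[segment][sl], axis=1)
    return float(speed.mean()), float(accel.mean())


def trunk_inclination_max(trial: MotionTrial, window: LiftWindow) -> float:
    """Maximum trunk inclination (deg) over the window; posture differences
    peak mid-lift, which is why the maximum rather than an endpoint is used."""
    return float(trial.trunk_inclination[window.start_frame : window.end_frame].max())


def extract_features(trial: MotionTrial, window: LiftWindow) -> pd.Series:
    """Assemble the full 223-entry feature pool for one lift window.

    Returns a Series indexed by :data:`FEATURE_NAMES`, in registry order.
    """
    start, last = window.start_frame, window.last_frame()
    values: list[float] = []
    movements: list[float] = []
    for joint in JOINTS:
        angles = trial.joint_angle[joint]
        movements.extend(angles[last] - angles[start])
    values.extend(movements)
    values.extend(abs(m) for m in movements)
    sl = slice(window.start_frame, window.end_frame)
    for seg in SEGMENTS:
        values.append(float(np.linalg.norm(trial.segment_vel[seg][sl], axis=1).mean()))
    for seg in SEGMENTS:
        values.append(float(np.linalg.norm(trial.segment_acc[seg][sl], axis=1).mean()))
    params = estimate_parameters(trial, window)
    values.extend([
        params.height_start, params.height_end,
        params.horiz_start, params.horiz_end,
        params.asym_start, params.asym_end,
        params.vertical_displacement, params.asym_max, params.asym_diff,
    ])
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)


def published_feature_set(subproblem: str) -> FeatureSetSpec:
    """The feature subset selected for a subproblem (7/3/3/3 features)."""
    if subproblem not in _PUBLISHED_SETS:
        raise KeyError(
            f"unknown subproblem {subproblem!r}; expected one of {SUBPROBLEMS}"
        )
    return FeatureSetSpec(subproblem, _PUBLISHED_SETS[subproblem])


# --- labeled feature tables --------------------------------------------------

_LABEL_COLUMNS = (
    "participant_id", "posture", "twist", "vertical_movement",
    "weight", "source", "destination",
)


def feature_table(
    pairs: Iterable[tuple[MotionTrial, "GroundTruth"]],
    windows: str = "truth",
    detect_window: int = 30,
) -> pd.DataFrame:
    """Build a labeled feature table from (trial, ground truth) pairs.

    One row per lift: label columns (participant, posture, twist, vertical
    movement category ``<source>_to_<destination>``, weight class), the 223
    pool features, and ``trunk_inclination_max``. ``windows`` selects whether
    features are computed on the ground-truth window (``"truth"``) or on the
    automatically detected one (``"detected"``).
    """
    if windows not in ("truth", "detected"):
        raise ValueError("windows must be 'truth' or 'detected'")
    rows: list[dict] = []
    for trial, truth in pairs:
        if windows == "truth":
            window = truth.true_window
        else:
            window = detect_lift(trial, window=detect_window)
        row: dict = {
            "participant_id": trial.participant_id,
            "posture": truth.posture,
            "twist": truth.twist,
            "vertical_movement": f"{truth.source}_to_{truth.destination}",
            "weight": f"{truth.weight}kg",
            "source": truth.source,
            "destination": truth.destination,
        }
        row.update(extract_features(trial, window).to_dict())
        row[TRUNK_INCLINATION_FEATURE] = trunk_inclination_max(trial, window)
        rows.append(row)
    columns = list(_LABEL_COLUMNS) + list(FEATURE_NAMES) + [TRUNK_INCLINATION_FEATURE]
    return pd.DataFrame(rows, columns=columns)
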