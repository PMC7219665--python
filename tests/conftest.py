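"""Shared fixtures and independent geometry helpers for the test suite."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from liftchar.synthetic_lifts import LiftSpec, generate_trial
from liftchar.trial_model import JOINTS, SEGMENTS, MotionTrial


# ---------------------------------------------------------------------------
# Minimal hand-built trials (for unit examples that need exact geometry)
# ---------------------------------------------------------------------------

def make_minimal_trial(
    n: int = 12,
    sample_rate: float = 60.0,
    com=None,
    lhand=None,
    rhand=None,
    lfoot=None,
    rfoot=None,
    lheading=None,
    rheading=None,
) -> MotionTrial:
    """A valid trial with explicit COM/hand/foot geometry and zeroed segments."""

    def series(default, given):
        if given is None:
            return np.tile(np.asarray(default, dtype=float), (n, 1))
        arr = np.asarray(given, dtype=float)
        return np.tile(arr, (n, 1)) if arr.ndim == 1 else arr.copy()

    zeros3 = np.zeros((n, 3))
    return MotionTrial(
        participant_id="unit",
        sample_rate=sample_rate,
        timestamps=np.arange(n) / sample_rate,
        com=series([0.0, 0.0, 1.0], com),
        hand_pos={
            "left": series([0.1, 0.2, 0.8], lhand),
            "right": series([0.1, -0.2, 0.8], rhand),
        },
        foot_pos={
            "left": series([0.0, 0.1, 0.0], lfoot),
            "right": series([0.0, -0.1, 0.0], rfoot),
        },
        foot_heading={
            "left": series([1.0, 0.0], lheading),
            "right": series([1.0, 0.0], rheading),
        },
        segment_pos={s: zeros3.copy() for s in SEGMENTS},
        segment_vel={s: zeros3.copy() for s in SEGMENTS},
        segment_acc={s: zeros3.copy() for s in SEGMENTS},
        joint_angle={j: zeros3.copy() for j in JOINTS},
        trunk_inclination=np.zeros(n),
    )


# ---------------------------------------------------------------------------
# Whole-scene transforms (independent of the package's internals)
# ---------------------------------------------------------------------------

def transform_trial(trial: MotionTrial, fn_pos, fn_heading=None) -> MotionTrial:
    """Apply a position transform (and optionally a heading transform) to
    every spatial series of a trial. Velocities/accelerations get the linear
    part of ``fn_pos`` applied via ``fn_pos(v) - fn_pos(0)``."""
    origin = fn_pos(np.zeros((1, 3)))

    def linear(arr):
        return fn_pos(arr) - origin

    fh = fn_heading or (lambda h: h)
    return dataclasses.replace(
        trial,
        com=fn_pos(trial.com),
        hand_pos={k: fn_pos(v) for k, v in trial.hand_pos.items()},
        foot_pos={k: fn_pos(v) for k, v in trial.foot_pos.items()},
        foot_heading={k: fh(v) for k, v in trial.foot_heading.items()},
        segment_pos={k: fn_pos(v) for k, v in trial.segment_pos.items()},
        segment_vel={k: linear(v) for k, v in trial.segment_vel.items()},
        segment_acc={k: linear(v) for k, v in trial.segment_acc.items()},
    )


def translate_trial(trial: MotionTrial, offset) -> MotionTrial:
    offset = np.asarray(offset, dtype=float)
    return transform_trial(trial, lambda p: p + offset)


def rotate_trial(trial: MotionTrial, angle_deg: float) -> MotionTrial:
    """Rotate the whole scene about the vertical axis through the origin."""
    a = np.radians(angle_deg)
    rot3 = np.array(
        [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )
    rot2 = rot3[:2, :2]
    return transform_trial(
        trial, lambda p: p @ rot3.T, fn_heading=lambda h: h @ rot2.T
    )


def scale_trial(trial: MotionTrial, s: float) -> MotionTrial:
    return transform_trial(trial, lambda p: p * s)


def mirror_trial(trial: MotionTrial) -> MotionTrial:
    """Mirror the scene across the XZ plane (negate every Y component)."""
    flip3 = np.array([1.0, -1.0, 1.0])
    flip2 = np.array([1.0, -1.0])
    return transform_trial(
        trial, lambda p: p * flip3, fn_heading=lambda h: h * flip2
    )


# ---------------------------------------------------------------------------
# Canonical synthetic trials
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def clean_floor_chest():
    """Noise-free straight floor-to-chest squat lift with ground truth."""
    spec = LiftSpec("floor", "chest", posture="squatting", twist="straight",
                    noise_sd=0.0, seed=11)
    return generate_trial(spec)


@pytest.fixture(scope="session")
def clean_twist_left():
    """Noise-free twist-left floor-to-chest lift with ground truth."""
    spec = LiftSpec("floor", "chest", posture="squatting", twist="left",
                    noise_sd=0.0, seed=12)
    return generate_trial(spec)


@pytest.fixture(scope="session")
def clean_twist_right():
    spec = LiftSpec("floor", "chest", posture="squatting", twist="right",
                    noise_sd=0.0, seed=12)
    return generate_trial(spec)
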