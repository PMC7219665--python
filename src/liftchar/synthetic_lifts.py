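"""Synthetic lifting-trial generator with exact ground truth.

Emulates the study protocol this package targets: a participant standing at
the origin (facing +X) moves a crate between four vertical levels (floor,
knee, chest, head shelves) using a squatting or stooping posture, twisting
45 degrees left or right when source and destination shelves differ in
heading, with a 3 kg or 10 kg load. One lift per trial; the hands start and
end relaxed at the sides.

The generator is built so that downstream stages are testable against known
truth:

* hand/object endpoint positions hit the protocol reference geometry exactly
  when ``noise_sd = 0`` (heights 0.30/0.84/1.38/1.87 m, horizontal rest
  distances 0.30/0.50/0.45/0.45 m, twist offset exactly 45 degrees);
* the COM-to-hands distance has, by construction, exactly one peak at grasp
  and one at release: the arms are maximally extended at those frames and the
  object is pulled in toward the trunk mid-carry;
* squat and stoop produce distinct joint-angle profiles (knee/hip flexion
  dominant vs. trunk inclination dominant with near-straight knees);
* the load affects only movement speed (10 kg lifts are slower), never
  geometry;
* everything is seeded and reproducible.

Trajectories use classic minimum-jerk interpolation between rest, grasp and
release postures. Positions receive isotropic Gaussian noise of standard
deviation ``noise_sd``; velocities and accelerations are finite differences
of the noise-free trajectories plus proportionally scaled noise, emulating
the smoothed kinematics a sensor-fusion engine outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from .lift_parameters import REFERENCE_HEIGHTS, REFERENCE_HORIZONTAL
from .trial_model import (
    JOINTS,
    LEVELS,
    POSTURES,
    SEGMENTS,
    TWISTS,
    WEIGHTS,
    LiftWindow,
    MotionTrial,
    TrialMetadata,
)

__all__ = [
    "LiftSpec",
    "GroundTruth",
    "ProtocolSpec",
    "LiftCensusRow",
    "LIFT_CENSUS",
    "MAIN_LIFT_TYPES",
    "total_recorded_lifts",
    "min_jerk",
    "generate_trial",
    "generate_dataset",
    "iter_dataset",
    "main_lift_templates",
]

# --- protocol constants ----------------------------------------------------

#: Angular offset between the two shelves (degrees, counterclockwise from
#: above for a twist to the left).
SHELF_ANGLE_DEG = 45.0

#: Duration of the reach (rest -> grasp) and return (release -> rest) phases.
REACH_DURATION = 1.0
RETURN_DURATION = 1.0

#: Light (3 kg) lifts are briskly executed: the lift phase is shortened by
#: this factor relative to the nominal duration used for 10 kg lifts.
LIGHT_LOAD_SPEED_FACTOR = 0.85

#: Mid-carry pull-in of the object toward the COM (fraction of the
#: COM->object vector removed at the midpoint of the carry).
PULL_IN = 0.45

#: Horizontal half-distance between the hands on the crate handles (m).
HALF_GRIP = 0.165

ANALYSIS_RATE = 60.0


# --- specs and ground truth ------------------------------------------------

@dataclass(frozen=True)
class LiftSpec:
    """Parameters of one synthetic lifting trial."""

    source: str
    destination: str
    posture: str = "squatting"
    twist: str = "straight"
    weight: int = 10                 # kg, 3 or 10
    lift_duration: float = 2.5       # s, nominal (10 kg) carry duration
    pre_rest: float = 1.2            # s of rest before the reach
    post_rest: float = 2.0           # s of rest after the return
    noise_sd: float = 0.005          # m, isotropic position noise
    seed: int = 0
    false_start: bool = False        # early reach + hold before the lift
    sample_rate: float = ANALYSIS_RATE

    def __post_init__(self) -> None:
        if self.source not in LEVELS or self.destination not in LEVELS:
            raise ValueError(f"levels must be in {LEVELS}")
        if self.posture not in POSTURES:
            raise ValueError(f"posture must be in {POSTURES}")
        if self.twist not in TWISTS:
            raise ValueError(f"twist must be in {TWISTS}")
        if self.weight not in WEIGHTS:
            raise ValueError(f"weight must be in {WEIGHTS}")
        if self.lift_duration <= 0:
            raise ValueError("lift_duration must be positive")
        if self.pre_rest < 0 or self.post_rest < 0:
            raise ValueError("rest durations must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side labels standing in for manually annotated truth."""

    true_window: LiftWindow
    true_asym_start: float
    true_asym_end: float
    true_asymmetry: float            # endpoint angle of larger magnitude
    true_height_start: float
    true_height_end: float
    true_horiz_start: float
    true_horiz_end: float
    source: str
    destination: str
    posture: str
    twist: str
    weight: int

    def to_metadata(self, participant_id: str, sample_rate: float) -> TrialMetadata:
        return TrialMetadata(
            participant_id=participant_id,
            sample_rate=sample_rate,
            posture=self.posture,
            twist=self.twist,
            source=self.source,
            destination=self.destination,
            weight=self.weight,
            ground_truth_window=self.true_window,
        )


# --- minimum jerk kernel ---------------------------------------------------

def min_jerk(p0, p1, T: float, t):
    """Minimum-jerk interpolation between two points.

    ``p0 + (p1 - p0) * (10 tau^3 - 15 tau^4 + 6 tau^5)`` with ``tau = t/T``;
    endpoint positions are exact and endpoint velocities are zero. ``t`` may
    be a scalar or an array in ``[0, T]``.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > T):
        raise ValueError(f"t must lie in [0, {T}]")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    tau = t_arr / T
    blend = tau**3 * (10.0 + tau * (-15.0 + 6.0 * tau))
    if blend.ndim == 0:
        return p0 + (p1 - p0) * float(blend)
    return p0 + (p1 - p0) * blend[:, None]


# --- trial synthesis -------------------------------------------------------

_POSTURE_PROFILE = {
    # posture -> (knee amp, hip amp, trunk amp, pelvis dip fraction)
    "squatting": (130.0, 100.0, 20.0, 0.42),
    "stooping": (12.0, 95.0, 68.0, 0.10),
    "neither": (45.0, 55.0, 35.0, 0.20),
}

_TWIST_SIGN = {"left": 1.0, "right": -1.0, "straight": 0.0}


def _level_point(level: str, angle_deg: float) -> np.ndarray:
    """Nominal object position for a level, rotated about the feet midpoint."""
    h = REFERENCE_HORIZONTAL[level]
    a = math.radians(angle_deg)
    return np.array([h * math.cos(a), h * math.sin(a), REFERENCE_HEIGHTS[level]])


def generate_trial(
    spec: LiftSpec,
    participant_id: str = "P01",
    height_scale: float = 1.0,
) -> tuple[MotionTrial, GroundTruth]:
    """Synthesize one lifting trial and its ground truth.

    ``height_scale`` scales the participant's body dimensions (limb lengths,
    rest posture) but never the shelf geometry: the hands always reach the
    protocol's reference heights exactly. Identical spec and seed give
    bit-identical trials.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    s = height_scale

    eff_lift = spec.lift_duration * (
        1.0 if spec.weight >= 6 else LIGHT_LOAD_SPEED_FACTOR
    )
    n_pre = round(spec.pre_rest * fs)
    n_reach = max(2, round(REACH_DURATION * fs))
    n_lift = max(2, round(eff_lift * fs))
    n_ret = max(2, round(RETURN_DURATION * fs))
    n_post = round(spec.post_rest * fs)
    g = n_pre + n_reach            # grasp frame (true start)
    r = g + n_lift                 # release frame (true end-of-lift state)
    n = r + n_ret + n_post + 1
    t = np.arange(n) / fs

    # endpoint geometry: the participant faces the lower endpoint; the
    # higher endpoint is rotated by the shelf offset for twisting lifts
    h_src = REFERENCE_HEIGHTS[spec.source]
    h_dst = REFERENCE_HEIGHTS[spec.destination]
    twist_angle = _TWIST_SIGN[spec.twist] * SHELF_ANGLE_DEG
    if h_src <= h_dst:
        theta_src, theta_dst = 0.0, twist_angle
    else:
        theta_src, theta_dst = twist_angle, 0.0
    p_src = _level_point(spec.source, theta_src)
    p_dst = _level_point(spec.destination, theta_dst)

    m_rest = np.array([0.06 * s, 0.0, 0.70 * s])

    # --- nominal hands-midpoint path (straight min-jerk carry) -------------
    m_nom = np.empty((n, 3))
    m_nom[:n_pre] = m_rest
    reach_from = m_rest
    if spec.false_start and n_pre >= round(1.0 * fs):
        # over-anticipated start: the hands reach all the way to the object
        # early and hold there, creating a distance plateau with no local
        # maximum left at the true start (the release peak is unaffected)
        e0 = n_pre // 4
        n_early = min(round(0.6 * fs), n_pre - e0 - 1)
        early = p_src
        tt = (np.arange(e0, e0 + n_early + 1) - e0) / fs
        m_nom[e0 : e0 + n_early + 1] = min_jerk(m_rest, early, n_early / fs, tt)
        m_nom[e0 + n_early + 1 : n_pre] = early
        reach_from = early
    tt = (np.arange(n_pre, g) - n_pre) / fs
    m_nom[n_pre:g] = min_jerk(reach_from, p_src, n_reach / fs, tt)
    tt = (np.arange(g, r + 1) - g) / fs
    m_nom[g : r + 1] = min_jerk(p_src, p_dst, n_lift / fs, tt)
    tt = (np.arange(r + 1, r + n_ret + 1) - r) / fs
    m_nom[r + 1 : r + n_ret + 1] = min_jerk(p_dst, m_rest, n_ret / fs, tt)
    m_nom[r + n_ret + 1 :] = m_rest

    # --- body posture driven by how low the object is -----------------------
    z_nom = m_nom[:, 2]
    depth = np.clip((1.45 * s - z_nom) / (1.15 * s), 0.0, 1.0)
    knee_amp, hip_amp, trunk_amp, dip = _POSTURE_PROFILE[spec.posture]
    knee = knee_amp * depth
    hip = hip_amp * depth
    trunk = trunk_amp * depth + 2.0

    pelvis_rest = np.array([0.02 * s, 0.0, 0.93 * s])
    pelvis = np.column_stack(
        [
            0.02 * s + 0.05 * s * depth,
            np.zeros(n),
            0.93 * s - dip * s * depth,
        ]
    )
    com_rest = np.array([0.01 * s, 0.0, 0.97 * s])
    com = com_rest + 0.6 * (pelvis - pelvis_rest)

    # --- final hands midpoint: pull the object toward the COM mid-carry ----
    m_mid = m_nom.copy()
    tau = (np.arange(g, r + 1) - g) / n_lift
    factor = 1.0 - PULL_IN * np.sin(np.pi * tau)
    m_mid[g : r + 1] = com[g : r + 1] + factor[:, None] * (
        m_nom[g : r + 1] - com[g : r + 1]
    )

    horiz = np.hypot(m_mid[:, 0], m_mid[:, 1])
    phi = np.degrees(np.arctan2(m_mid[:, 1], m_mid[:, 0]))
    phi[horiz < 1e-9] = 0.0
    phi_rad = np.radians(phi)
    u_perp = np.column_stack([-np.sin(phi_rad), np.cos(phi_rad), np.zeros(n)])
    lhand = m_mid + HALF_GRIP * u_perp
    rhand = m_mid - HALF_GRIP * u_perp

    # --- joint-angle profiles ----------------------------------------------
    engage = np.clip(np.linalg.norm(m_mid - m_rest, axis=1) / 0.25, 0.0, 1.0)
    shoulder = engage * (20.0 + 70.0 * np.clip((z_nom - 0.6 * s) / (1.3 * s), 0.0, 1.0))
    elbow = 35.0 * engage
    angle_sd = spec.noise_sd * 100.0  # deg of angle jitter per meter of noise

    joint_angle: dict[str, np.ndarray] = {
        j: np.zeros((n, 3)) for j in JOINTS
    }
    joint_angle["jRightKnee"][:, 2] = knee
    joint_angle["jLeftKnee"][:, 2] = 0.97 * knee
    joint_angle["jRightHip"][:, 2] = 0.96 * hip
    joint_angle["jLeftHip"][:, 2] = hip
    joint_angle["jRightShoulder"][:, 2] = shoulder
    joint_angle["jLeftShoulder"][:, 2] = 0.98 * shoulder
    joint_angle["jRightElbow"][:, 2] = elbow
    joint_angle["jLeftElbow"][:, 2] = elbow
    joint_angle["jRightAnkle"][:, 2] = 0.3 * knee
    joint_angle["jLeftAnkle"][:, 2] = 0.3 * knee
    joint_angle["jT9T8"][:, 0] = 0.6 * phi          # upper-body axial twist
    joint_angle["Pelvis_T8"][:, 1] = 0.4 * phi      # trunk twist vs. pelvis
    joint_angle["Vertical_Pelvis"][:, 1] = 0.25 * phi
    joint_angle["Vertical_T8"][:, 2] = trunk
    joint_angle["Vertical_Pelvis"][:, 2] = 0.35 * trunk
    joint_angle["jL5S1"][:, 2] = 0.45 * trunk
    joint_angle["jL4L3"][:, 2] = 0.20 * trunk
    joint_angle["jL1T12"][:, 2] = 0.15 * trunk
    joint_angle["jT1C7"][:, 2] = 0.10 * trunk
    joint_angle["T8_Head"][:, 2] = 5.0 * engage
    joint_angle["T8_RightUpperArm"][:, 2] = 0.9 * shoulder
    joint_angle["T8_LeftUpperArm"][:, 2] = 0.9 * shoulder
    if angle_sd > 0:
        for j in JOINTS:
            joint_angle[j] = joint_angle[j] + rng.normal(0.0, angle_sd, (n, 3))

    trunk_incl = trunk.copy()
    if angle_sd > 0:
        trunk_incl = trunk_incl + rng.normal(0.0, angle_sd, n)

    # --- segment positions ---------------------------------------------------
    theta_t = np.radians(trunk)
    phi_b = np.radians(0.5 * phi)
    head = pelvis + 0.68 * s * np.column_stack(
        [
            np.sin(theta_t) * np.cos(phi_b),
            np.sin(theta_t) * np.sin(phi_b),
            np.cos(theta_t),
        ]
    )
    lfoot = np.tile([0.0, 0.11 * s, 0.02], (n, 1))
    rfoot = np.tile([0.0, -0.11 * s, 0.02], (n, 1))

    seg_pos: dict[str, np.ndarray] = {}
    for name, frac in (("L5", 0.08), ("L3", 0.18), ("T12", 0.30), ("T8", 0.45),
                       ("Neck", 0.85)):
        seg_pos[name] = pelvis + frac * (head - pelvis)
    seg_pos["Pelvis"] = pelvis
    seg_pos["Head"] = head
    t8 = seg_pos["T8"]
    rot = np.column_stack([np.cos(phi_b), np.sin(phi_b)])
    for side, sign in (("Left", 1.0), ("Right", -1.0)):
        lateral = sign * 0.19 * s
        sh = t8 + np.column_stack(
            [-lateral * rot[:, 1], lateral * rot[:, 0], np.full(n, 0.12 * s)]
        )
        hand = lhand if side == "Left" else rhand
        el = 0.5 * (sh + hand) + np.array([0.0, 0.0, -0.06 * s])
        seg_pos[f"{side}Shoulder"] = sh
        seg_pos[f"{side}UpperArm"] = 0.5 * (sh + el)
        seg_pos[f"{side}Forearm"] = 0.5 * (el + hand)
        seg_pos[f"{side}Hand"] = hand
        foot = lfoot if side == "Left" else rfoot
        knee_fwd = {"squatting": 1.0, "stooping": 0.15, "neither": 0.4}[spec.posture]
        knee_pt = 0.5 * (pelvis + foot) + np.column_stack(
            [0.18 * s * depth * knee_fwd, np.zeros(n), np.zeros(n)]
        )
        seg_pos[f"{side}UpperLeg"] = 0.5 * (pelvis + knee_pt)
        seg_pos[f"{side}LowerLeg"] = 0.5 * (knee_pt + foot)
        seg_pos[f"{side}Foot"] = foot
        seg_pos[f"{side}Toe"] = foot + np.array([0.12 * s, 0.0, -0.01])

    # --- differentiate clean kinematics, then add measurement noise ---------
    seg_vel: dict[str, np.ndarray] = {}
    seg_acc: dict[str, np.ndarray] = {}
    for name in SEGMENTS:
        vel = np.gradient(seg_pos[name], axis=0) * fs
        acc = np.gradient(vel, axis=0) * fs
        seg_vel[name] = vel
        seg_acc[name] = acc

    def noisy(arr: np.ndarray, sd: float) -> np.ndarray:
        if sd <= 0:
            return arr
        return arr + rng.normal(0.0, sd, arr.shape)

    com_out = noisy(com, spec.noise_sd)
    lhand_out = noisy(lhand, spec.noise_sd)
    rhand_out = noisy(rhand, spec.noise_sd)
    lfoot_out = noisy(lfoot, spec.noise_sd)
    rfoot_out = noisy(rfoot, spec.noise_sd)
    for name in SEGMENTS:
        if name == "LeftHand":
            seg_pos[name] = lhand_out
        elif name == "RightHand":
            seg_pos[name] = rhand_out
        elif name == "LeftFoot":
            seg_pos[name] = lfoot_out
        elif name == "RightFoot":
            seg_pos[name] = rfoot_out
        else:
            seg_pos[name] = noisy(seg_pos[name], spec.noise_sd)
        seg_vel[name] = noisy(seg_vel[name], 4.0 * spec.noise_sd)
        seg_acc[name] = noisy(seg_acc[name], 20.0 * spec.noise_sd)

    heading = np.tile([1.0, 0.0], (n, 1))
    trial = MotionTrial(
        participant_id=participant_id,
        sample_rate=fs,
        timestamps=t,
        com=com_out,
        hand_pos={"left": lhand_out, "right": rhand_out},
        foot_pos={"left": lfoot_out, "right": rfoot_out},
        foot_heading={"left": heading, "right": heading.copy()},
        segment_pos=seg_pos,
        segment_vel=seg_vel,
        segment_acc=seg_acc,
        joint_angle=joint_angle,
        trunk_inclination=trunk_incl,
    )

    asym_start, asym_end = theta_src, theta_dst
    asym_max = asym_start if abs(asym_start) >= abs(asym_end) else asym_end
    truth = GroundTruth(
        true_window=LiftWindow.from_frames(g, r + 1, fs),
        true_asym_start=asym_start,
        true_asym_end=asym_end,
        true_asymmetry=asym_max,
        true_height_start=h_src,
        true_height_end=h_dst,
        true_horiz_start=REFERENCE_HORIZONTAL[spec.source],
        true_horiz_end=REFERENCE_HORIZONTAL[spec.destination],
        source=spec.source,
        destination=spec.destination,
        posture=spec.posture,
        twist=spec.twist,
        weight=spec.weight,
    )
    return trial, truth


# --- protocol census --------------------------------------------------------

@dataclass(frozen=True)
class LiftCensusRow:
    """Planned and actually recorded occurrence counts for one lift type."""

    group: str                 # "main", "extra" or "unplanned"
    source: str
    destination: str
    posture: str
    twist: str
    weight: int
    planned: int
    occurred: int


def _census(rows: Iterable[tuple]) -> tuple[LiftCensusRow, ...]:
    return tuple(LiftCensusRow(*row) for row in rows)


#: Full study protocol census: the 30 main lift types, the extra lifts used
#: only as transitions, and the lifts performed by mistake, each with its
#: planned and recorded occurrence count across all 24 participants.
LIFT_CENSUS: tuple[LiftCensusRow, ...] = _census([
    # main lifts
    ("main", "floor", "chest", "squatting", "straight", 10, 51, 51),
    ("main", "floor", "chest", "stooping", "straight", 10, 50, 48),
    ("main", "knee", "chest", "squatting", "straight", 10, 51, 48),
    ("main", "knee", "chest", "stooping", "straight", 10, 50, 50),
    ("main", "chest", "head", "neither", "straight", 10, 48, 46),
    ("main", "floor", "chest", "squatting", "straight", 3, 48, 48),
    ("main", "floor", "chest", "stooping", "straight", 3, 48, 50),
    ("main", "chest", "floor", "squatting", "straight", 10, 48, 48),
    ("main", "chest", "floor", "stooping", "straight", 10, 51, 48),
    ("main", "chest", "knee", "squatting", "straight", 10, 50, 48),
    ("main", "chest", "knee", "stooping", "straight", 10, 49, 49),
    ("main", "head", "chest", "neither", "straight", 10, 48, 46),
    ("main", "chest", "floor", "squatting", "straight", 3, 48, 48),
    ("main", "chest", "floor", "stooping", "straight", 3, 48, 50),
    ("main", "floor", "chest", "squatting", "left", 10, 49, 49),
    ("main", "floor", "chest", "stooping", "left", 10, 48, 48),
    ("main", "floor", "chest", "squatting", "right", 10, 48, 47),
    ("main", "floor", "chest", "stooping", "right", 10, 48, 48),
    ("main", "knee", "chest", "squatting", "left", 10, 49, 51),
    ("main", "knee", "chest", "stooping", "left", 10, 48, 48),
    ("main", "knee", "chest", "squatting", "right", 10, 48, 48),
    ("main", "knee", "chest", "stooping", "right", 10, 49, 49),
    ("main", "chest", "floor", "squatting", "left", 10, 48, 48),
    ("main", "chest", "floor", "stooping", "left", 10, 48, 48),
    ("main", "chest", "floor", "squatting", "right", 10, 48, 48),
    ("main", "chest", "floor", "stooping", "right", 10, 48, 48),
    ("main", "chest", "knee", "squatting", "left", 10, 48, 48),
    ("main", "chest", "knee", "stooping", "left", 10, 48, 47),
    ("main", "chest", "knee", "squatting", "right", 10, 48, 50),
    ("main", "chest", "knee", "stooping", "right", 10, 48, 48),
    # extra (transition-only) lifts
    ("extra", "knee", "floor", "squatting", "straight", 10, 1, 1),
    ("extra", "knee", "floor", "stooping", "straight", 10, 1, 1),
    ("extra", "floor", "head", "squatting", "straight", 10, 1, 1),
    ("extra", "floor", "knee", "stooping", "straight", 10, 4, 4),
    ("extra", "head", "knee", "neither", "straight", 10, 1, 1),
    ("extra", "chest", "chest", "neither", "left", 10, 4, 4),
    ("extra", "chest", "chest", "neither", "right", 10, 9, 9),
    ("extra", "floor", "knee", "squatting", "left", 10, 2, 2),
    ("extra", "floor", "knee", "squatting", "right", 10, 1, 1),
    ("extra", "knee", "floor", "stooping", "left", 10, 1, 1),
    ("extra", "knee", "knee", "squatting", "left", 10, 1, 1),
    ("extra", "floor", "floor", "squatting", "left", 10, 1, 1),
    ("extra", "floor", "floor", "stooping", "left", 10, 1, 1),
    ("extra", "floor", "knee", "stooping", "right", 10, 1, 1),
    ("extra", "knee", "knee", "stooping", "right", 10, 1, 1),
    # unplanned lifts
    ("unplanned", "head", "chest", "neither", "straight", 3, 0, 2),
    ("unplanned", "chest", "head", "neither", "straight", 3, 0, 2),
    ("unplanned", "knee", "chest", "squatting", "straight", 3, 0, 2),
    ("unplanned", "chest", "knee", "squatting", "straight", 3, 0, 2),
])

#: The 30 main lift types (source, destination, posture, twist, weight).
MAIN_LIFT_TYPES: tuple[tuple[str, str, str, str, int], ...] = tuple(
    (row.source, row.destination, row.posture, row.twist, row.weight)
    for row in LIFT_CENSUS
    if row.group == "main"
)


def total_recorded_lifts() -> int:
    """Total number of lifting trials actually recorded in the study."""
    return sum(row.occurred for row in LIFT_CENSUS)


# --- datasets ---------------------------------------------------------------

def main_lift_templates(noise_sd: float = 0.005) -> tuple[LiftSpec, ...]:
    """One template spec per main lift type, at the default study conditions."""
    return tuple(
        LiftSpec(source=src, destination=dst, posture=posture, twist=twist,
                 weight=weight, noise_sd=noise_sd)
        for src, dst, posture, twist, weight in MAIN_LIFT_TYPES
    )


@dataclass(frozen=True)
class ProtocolSpec:
    """A whole experiment: lift templates x repetitions x participants.

    The defaults reproduce the main-lift block of the study protocol: 30 lift
    types, 2 repetitions each, 24 participants (1440 trials), with per-trial
    seeded jitter of durations and per-participant body scaling.
    """

    templates: tuple[tuple[LiftSpec, int], ...] = field(
        default_factory=lambda: tuple((t, 2) for t in main_lift_templates())
    )
    n_participants: int = 24
    height_range: tuple[float, float] = (0.93, 1.07)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if any(reps < 1 for _, reps in self.templates):
            raise ValueError("repetitions must be >= 1")


def iter_dataset(protocol: ProtocolSpec) -> Iterator[tuple[MotionTrial, GroundTruth]]:
    """Stream the trials of a protocol (randomized per-participant order)."""
    rng = np.random.default_rng(protocol.master_seed)
    lo, hi = protocol.height_range
    for p in range(protocol.n_participants):
        pid = f"P{p + 1:02d}"
        height_scale = float(rng.uniform(lo, hi))
        expanded = [tpl for tpl, reps in protocol.templates for _ in range(reps)]
        order = rng.permutation(len(expanded))
        for idx in order:
            tpl = expanded[idx]
            spec = replace(
                tpl,
                seed=int(rng.integers(2**31)),
                lift_duration=tpl.lift_duration * float(rng.uniform(0.95, 1.05)),
                pre_rest=tpl.pre_rest * float(rng.uniform(0.9, 1.1)),
                post_rest=tpl.post_rest * float(rng.uniform(0.9, 1.1)),
            )
            yield generate_trial(spec, participant_id=pid, height_scale=height_scale)


def generate_dataset(protocol: ProtocolSpec) -> list[tuple[MotionTrial, GroundTruth]]:
    """Materialize a whole protocol as a list (see :func:`iter_dataset`)."""
    return list(iter_dataset(protocol))
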