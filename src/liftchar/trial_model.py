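"""Data model for full-body kinematic lifting trials.

A :class:`MotionTrial` holds one pre-segmented lifting trial as produced by a
fused full-body inertial motion-capture system: per-frame center of mass,
hand and foot positions, foot headings, the position/velocity/acceleration of
23 named body segments, 28 named joint angles on three axes each, and the
trunk inclination (angle between the trunk longitudinal axis and vertical).

Coordinate convention (fixed for the whole package): right-handed axes with
+Z up; the floor plane is XY; +X is the nominal forward direction of a
participant standing at the origin. Positions are meters, velocities m/s,
accelerations m/s^2, angles degrees. Frames are 0-based and windows are
half-open ``[start, end)`` frame intervals; times are ``frame / sample_rate``
seconds.

Trials round-trip through a plain CSV table (one row per frame, canonical
column order) plus a YAML metadata sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SEGMENTS",
    "JOINTS",
    "JOINT_AXES",
    "LiftWindow",
    "MotionTrial",
    "TrialMetadata",
    "TrialFormatError",
    "TrialValidationError",
    "trial_columns",
    "load_trial",
    "save_trial",
    "downsample",
    "validate_trial",
]

# ---------------------------------------------------------------------------
# Registries
# ---------------------------------------------------------------------------

#: The 23 body segments of the biomechanical model (pelvis-up then limbs).
SEGMENTS: tuple[str, ...] = (
    "Pelvis", "L5", "L3", "T12", "T8", "Neck", "Head",
    "RightShoulder", "RightUpperArm", "RightForearm", "RightHand",
    "LeftShoulder", "LeftUpperArm", "LeftForearm", "LeftHand",
    "RightUpperLeg", "RightLowerLeg", "RightFoot", "RightToe",
    "LeftUpperLeg", "LeftLowerLeg", "LeftFoot", "LeftToe",
)

#: The 28 named joints whose angles are carried per trial: the 22 anatomical
#: joints of the skeletal model plus 6 ergonomic segment-pair angles
#: (trunk-relative and vertical-relative orientations). The exact vendor
#: joint list is not public; this registry is the package's documented
#: stand-in and is fixed so that feature names are stable across trials.
JOINTS: tuple[str, ...] = (
    "jL5S1", "jL4L3", "jL1T12", "jT9T8", "jT1C7", "jC1Head",
    "jRightC7Shoulder", "jRightShoulder", "jRightElbow", "jRightWrist",
    "jRightHip", "jRightKnee", "jRightAnkle", "jRightBallFoot",
    "jLeftC7Shoulder", "jLeftShoulder", "jLeftElbow", "jLeftWrist",
    "jLeftHip", "jLeftKnee", "jLeftAnkle", "jLeftBallFoot",
    "T8_Head", "T8_LeftUpperArm", "T8_RightUpperArm",
    "Pelvis_T8", "Vertical_Pelvis", "Vertical_T8",
)

#: Joint rotation axes. ax1 extends forward in the facing direction (axial
#: rotation for spinal joints), ax2 is vertical while standing, ax3 is the
#: lateral axis (flexion-extension).
JOINT_AXES: tuple[str, ...] = ("ax1", "ax2", "ax3")

SIDES: tuple[str, str] = ("left", "right")

_BASE_COLUMNS = (
    ["time"]
    + [f"com_{c}" for c in "xyz"]
    + [f"lhand_{c}" for c in "xyz"]
    + [f"rhand_{c}" for c in "xyz"]
    + [f"lfoot_{c}" for c in "xyz"]
    + [f"rfoot_{c}" for c in "xyz"]
    + ["lfoot_hx", "lfoot_hy", "rfoot_hx", "rfoot_hy"]
)

_SEG_FIELDS = ("px", "py", "pz", "vx", "vy", "vz", "ax", "ay", "az")


def trial_columns() -> list[str]:
    """Canonical column order of the trial CSV table."""
    cols = list(_BASE_COLUMNS)
    for seg in SEGMENTS:
        cols += [f"{seg}_{f}" for f in _SEG_FIELDS]
    for joint in JOINTS:
        cols += [f"{joint}_{ax}" for ax in JOINT_AXES]
    cols.append("trunk_incl")
    return cols


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class TrialFormatError(ValueError):
    """A trial file does not conform to the tabular format."""


class TrialValidationError(ValueError):
    """A trial violates a model invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LiftWindow:
    """Half-open frame interval ``[start_frame, end_frame)`` of a lift.

    The last frame belonging to the lift (the "end-of-lift state") is
    ``end_frame - 1``. ``start_time``/``end_time`` are the corresponding
    frame indices divided by the sample rate.
    """

    start_frame: int
    end_frame: int
    start_time: float
    end_time: float

    @classmethod
    def from_frames(cls, start: int, end: int, sample_rate: float) -> "LiftWindow":
        if not (0 <= start < end):
            raise ValueError(f"invalid window frames [{start}, {end})")
        return cls(int(start), int(end), start / sample_rate, end / sample_rate)

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    def last_frame(self) -> int:
        """Index of the final frame inside the window."""
        return self.end_frame - 1


POSTURES = ("squatting", "stooping", "neither")
TWISTS = ("left", "right", "straight")
LEVELS = ("floor", "knee", "chest", "head")
WEIGHTS = (3, 10)


@dataclass
class TrialMetadata:
    """Sidecar metadata: who was recorded, at what rate, and optional labels."""

    participant_id: str
    sample_rate: float
    posture: str | None = None
    twist: str | None = None
    source: str | None = None
    destination: str | None = None
    weight: int | None = None
    ground_truth_window: LiftWindow | None = None

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for name, value, vocab in (
            ("posture", self.posture, POSTURES),
            ("twist", self.twist, TWISTS),
            ("source", self.source, LEVELS),
            ("destination", self.destination, LEVELS),
            ("weight", self.weight, WEIGHTS),
        ):
            if value is not None and value not in vocab:
                raise ValueError(f"{name}={value!r} not in {vocab}")


@dataclass
class MotionTrial:
    """Frame-indexed kinematic record of one lifting trial.

    All per-frame arrays share the first dimension ``n_frames``. ``hand_pos``,
    ``foot_pos`` and ``foot_heading`` are keyed by side (``left``/``right``);
    segment and joint dictionaries are keyed by the registry names.
    """

    participant_id: str
    sample_rate: float
    timestamps: np.ndarray                      # (n,)
    com: np.ndarray                             # (n, 3)
    hand_pos: dict[str, np.ndarray]             # side -> (n, 3)
    foot_pos: dict[str, np.ndarray]             # side -> (n, 3)
    foot_heading: dict[str, np.ndarray]         # side -> (n, 2), unit norm
    segment_pos: dict[str, np.ndarray]          # segment -> (n, 3)
    segment_vel: dict[str, np.ndarray]
    segment_acc: dict[str, np.ndarray]
    joint_angle: dict[str, np.ndarray]          # joint -> (n, 3) degrees
    trunk_inclination: np.ndarray               # (n,) degrees

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Elapsed time from first to last frame, ``(n_frames - 1)/rate``."""
        return float(self.timestamps[-1] - self.timestamps[0])

    def _all_series(self) -> Iterable[tuple[str, np.ndarray]]:
        yield "timestamps", self.timestamps
        yield "com", self.com
        for side in SIDES:
            yield f"hand_pos[{side}]", self.hand_pos[side]
            yield f"foot_pos[{side}]", self.foot_pos[side]
            yield f"foot_heading[{side}]", self.foot_heading[side]
        for seg in SEGMENTS:
            yield f"segment_pos[{seg}]", self.segment_pos[seg]
            yield f"segment_vel[{seg}]", self.segment_vel[seg]
            yield f"segment_acc[{seg}]", self.segment_acc[seg]
        for joint in JOINTS:
            yield f"joint_angle[{joint}]", self.joint_angle[joint]
        yield "trunk_inclination", self.trunk_inclination


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_MAX_FINDINGS_PER_CHECK = 5


def validate_trial(trial: MotionTrial, heading_tol: float = 1e-6) -> list[str]:
    """Check every model invariant and report violations.

    Returns a list of human-readable findings naming the offending field and
    frame; an empty list means the trial is valid. This function reports
    rather than raises so callers can decide severity.
    """
    findings: list[str] = []
    n = trial.n_frames

    if trial.sample_rate <= 0:
        findings.append(f"sample_rate must be positive, got {trial.sample_rate}")
        return findings

    for name, arr in trial._all_series():
        if len(arr) != n:
            findings.append(f"{name}: length {len(arr)} != n_frames {n}")
    if findings:
        return findings  # frame-indexed checks below assume equal lengths

    ts = np.asarray(trial.timestamps, dtype=float)
    if n >= 2:
        diffs = np.diff(ts)
        bad = np.flatnonzero(diffs <= 0)
        for i in bad[:_MAX_FINDINGS_PER_CHECK]:
            findings.append(
                f"timestamps: not strictly increasing at frame {i + 1} "
                f"(dt={diffs[i]:.3g})"
            )
        expected = 1.0 / trial.sample_rate
        off = np.flatnonzero(np.abs(diffs - expected) > 1e-6 * expected + 1e-12)
        off = np.setdiff1d(off, bad)
        for i in off[:_MAX_FINDINGS_PER_CHECK]:
            findings.append(
                f"timestamps: spacing {diffs[i]:.9g} at frame {i + 1} != "
                f"1/sample_rate ({expected:.9g})"
            )

    for side in SIDES:
        norms = np.linalg.norm(trial.foot_heading[side], axis=1)
        bad = np.flatnonzero(np.abs(norms - 1.0) > heading_tol)
        for i in bad[:_MAX_FINDINGS_PER_CHECK]:
            findings.append(
                f"foot_heading[{side}]: norm {norms[i]:.6g} != 1 at frame {i}"
            )

    for name, arr in trial._all_series():
        finite = np.isfinite(arr)
        if not finite.all():
            frames = np.unique(np.nonzero(~finite)[0])
            for i in frames[:_MAX_FINDINGS_PER_CHECK]:
                findings.append(f"{name}: non-finite value at frame {i}")

    return findings


def _require_valid(trial: MotionTrial) -> MotionTrial:
    findings = validate_trial(trial)
    if findings:
        raise TrialValidationError("; ".join(findings))
    return trial


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def trial_to_frame(trial: MotionTrial) -> pd.DataFrame:
    """Flatten a trial into the canonical one-row-per-frame table."""
    data: dict[str, np.ndarray] = {"time": np.asarray(trial.timestamps, float)}
    for prefix, arr in (
        ("com", trial.com),
        ("lhand", trial.hand_pos["left"]),
        ("rhand", trial.hand_pos["right"]),
        ("lfoot", trial.foot_pos["left"]),
        ("rfoot", trial.foot_pos["right"]),
    ):
        for j, c in enumerate("xyz"):
            data[f"{prefix}_{c}"] = np.asarray(arr[:, j], float)
    for prefix, arr in (
        ("lfoot", trial.foot_heading["left"]),
        ("rfoot", trial.foot_heading["right"]),
    ):
        data[f"{prefix}_hx"] = np.asarray(arr[:, 0], float)
        data[f"{prefix}_hy"] = np.asarray(arr[:, 1], float)
    for seg in SEGMENTS:
        for arr, fields in (
            (trial.segment_pos[seg], _SEG_FIELDS[0:3]),
            (trial.segment_vel[seg], _SEG_FIELDS[3:6]),
            (trial.segment_acc[seg], _SEG_FIELDS[6:9]),
        ):
            for j, f in enumerate(fields):
                data[f"{seg}_{f}"] = np.asarray(arr[:, j], float)
    for joint in JOINTS:
        for j, ax in enumerate(JOINT_AXES):
            data[f"{joint}_{ax}"] = np.asarray(trial.joint_angle[joint][:, j], float)
    data["trunk_incl"] = np.asarray(trial.trunk_inclination, float)
    return pd.DataFrame(data, columns=trial_columns())


def trial_from_frame(df: pd.DataFrame, meta: TrialMetadata) -> MotionTrial:
    """Build a validated trial from a canonical table and its metadata."""
    missing = [c for c in trial_columns() if c not in df.columns]
    if missing:
        raise TrialFormatError(f"missing required column(s): {', '.join(missing[:8])}")

    def vec3(prefix: str, fields: tuple[str, ...]) -> np.ndarray:
        return df[[f"{prefix}_{f}" for f in fields]].to_numpy(dtype=float)

    trial = MotionTrial(
        participant_id=meta.participant_id,
        sample_rate=meta.sample_rate,
        timestamps=df["time"].to_numpy(dtype=float),
        com=vec3("com", ("x", "y", "z")),
        hand_pos={"left": vec3("lhand", ("x", "y", "z")),
                  "right": vec3("rhand", ("x", "y", "z"))},
        foot_pos={"left": vec3("lfoot", ("x", "y", "z")),
                  "right": vec3("rfoot", ("x", "y", "z"))},
        foot_heading={"left": vec3("lfoot", ("hx", "hy")),
                      "right": vec3("rfoot", ("hx", "hy"))},
        segment_pos={s: vec3(s, _SEG_FIELDS[0:3]) for s in SEGMENTS},
        segment_vel={s: vec3(s, _SEG_FIELDS[3:6]) for s in SEGMENTS},
        segment_acc={s: vec3(s, _SEG_FIELDS[6:9]) for s in SEGMENTS},
        joint_angle={j: vec3(j, JOINT_AXES) for j in JOINTS},
        trunk_inclination=df["trunk_incl"].to_numpy(dtype=float),
    )
    return _require_valid(trial)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def save_trial(trial: MotionTrial, meta: TrialMetadata, path: str | Path) -> Path:
    """Write the trial table (CSV) and metadata sidecar (YAML).

    Floats are written with Python's shortest round-trip representation, so
    save -> load -> save is byte-stable.
    """
    path = Path(path)
    trial_to_frame(trial).to_csv(path, index=False)
    doc: dict = {
        "participant_id": meta.participant_id,
        "sample_rate": float(meta.sample_rate),
    }
    labels = {
        k: v
        for k, v in (
            ("posture", meta.posture),
            ("twist", meta.twist),
            ("source", meta.source),
            ("destination", meta.destination),
            ("weight", meta.weight),
        )
        if v is not None
    }
    if labels:
        doc["labels"] = labels
    if meta.ground_truth_window is not None:
        doc["ground_truth_window"] = {
            "start_frame": int(meta.ground_truth_window.start_frame),
            "end_frame": int(meta.ground_truth_window.end_frame),
        }
    _sidecar_path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def load_trial(path: str | Path) -> tuple[MotionTrial, TrialMetadata]:
    """Load and validate a trial table and its YAML sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise TrialFormatError(f"trial table not found: {path}")
    if not sidecar.exists():
        raise TrialFormatError(f"metadata sidecar not found: {sidecar}")
    doc = yaml.safe_load(sidecar.read_text())
    if not isinstance(doc, dict) or "participant_id" not in doc or "sample_rate" not in doc:
        raise TrialFormatError(f"sidecar {sidecar} missing participant_id/sample_rate")
    labels = doc.get("labels") or {}
    gtw = doc.get("ground_truth_window")
    window = None
    if gtw is not None:
        window = LiftWindow.from_frames(
            gtw["start_frame"], gtw["end_frame"], float(doc["sample_rate"])
        )
    meta = TrialMetadata(
        participant_id=str(doc["participant_id"]),
        sample_rate=float(doc["sample_rate"]),
        posture=labels.get("posture"),
        twist=labels.get("twist"),
        source=labels.get("source"),
        destination=labels.get("destination"),
        weight=labels.get("weight"),
        ground_truth_window=window,
    )
    # round_trip parsing: the shortest-repr floats written by save_trial must
    # parse back to bit-identical values (byte-stable save -> load -> save)
    df = pd.read_csv(path, float_precision="round_trip")
    return trial_from_frame(df, meta), meta


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def downsample(trial: MotionTrial, factor: int) -> MotionTrial:
    """Keep every ``factor``-th frame starting at frame 0.

    Plain decimation (no anti-alias filtering); the sample rate is divided by
    ``factor``. The result must retain at least two frames.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor!r}")
    if factor == 1:
        return trial
    n_out = -(-trial.n_frames // factor)  # ceil
    if n_out < 2:
        raise ValueError(
            f"downsampling {trial.n_frames} frames by {factor} leaves {n_out} frame(s)"
        )
    sl = slice(None, None, int(factor))

    def cut(d: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        return {k: v[sl] for k, v in d.items()}

    return MotionTrial(
        participant_id=trial.participant_id,
        sample_rate=trial.sample_rate / factor,
        timestamps=trial.timestamps[sl],
        com=trial.com[sl],
        hand_pos=cut(trial.hand_pos),
        foot_pos=cut(trial.foot_pos),
        foot_heading=cut(trial.foot_heading),
        segment_pos=cut(trial.segment_pos),
        segment_vel=cut(trial.segment_vel),
        segment_acc=cut(trial.segment_acc),
        joint_angle=cut(trial.joint_angle),
        trunk_inclination=trial.trunk_inclination[sl],
    )
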