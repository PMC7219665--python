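"""Lift start/end detection from the COM-to-hands distance signal.

The detector exploits a balance argument: while handling a load at arm's
length the body keeps its center of mass over the feet, so at the moments of
grasp and release the hands are at their furthest from the center of mass.
The per-frame mean distance from the COM to the two hands is smoothed with a
centered moving average and the two most topographically prominent local
maxima of the smoothed signal mark the beginning and end of the lift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .trial_model import LiftWindow, MotionTrial

__all__ = [
    "LiftWindow",
    "Peak",
    "PeakSet",
    "NoLiftError",
    "com_hand_distance",
    "moving_average",
    "find_peaks_with_prominence",
    "detect_lift",
    "detection_error",
]

#: Default smoothing window (frames); 0.5 s at the 60 Hz analysis rate.
DEFAULT_SMOOTHING_WINDOW = 30


class NoLiftError(RuntimeError):
    """Raised when fewer than two peaks exist, i.e. no lift was found."""


@dataclass(frozen=True)
class Peak:
    frame: int
    height: float
    prominence: float


@dataclass(frozen=True)
class PeakSet:
    """Local maxima of a series with their topographic prominences.

    Peaks are ordered by frame. Prominence is the peak height minus the
    higher of the two minimal saddles separating the peak from higher
    terrain, with the series ends acting as terrain boundaries; the global
    maximum's prominence is its height minus the global minimum.
    """

    peaks: tuple[Peak, ...]

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def most_prominent(self, k: int) -> list[Peak]:
        """The ``k`` peaks of highest prominence, ties broken toward the
        earlier frame, returned in frame order."""
        ranked = sorted(self.peaks, key=lambda p: (-p.prominence, p.frame))[:k]
        return sorted(ranked, key=lambda p: p.frame)


def com_hand_distance(trial: MotionTrial) -> np.ndarray:
    """Mean 3D Euclidean distance from the COM to the two hands, per frame."""
    d_left = np.linalg.norm(trial.hand_pos["left"] - trial.com, axis=1)
    d_right = np.linalg.norm(trial.hand_pos["right"] - trial.com, axis=1)
    return 0.5 * (d_left + d_right)


def moving_average(series: np.ndarray, window: int = DEFAULT_SMOOTHING_WINDOW) -> np.ndarray:
    """Centered moving mean with symmetrically shrinking edge windows.

    At index ``i`` the mean is taken over ``[i - r, i + r]`` with radius
    ``r = min(window // 2, i, n - 1 - i)``, so the output has the same length
    as the input, the filter introduces no phase lag, and a window of 1 is
    the identity.
    """
    series = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    n = len(series)
    if n == 0:
        return series.copy()
    half = window // 2
    # cumulative-sum evaluation of the shrinking symmetric window
    csum = np.concatenate(([0.0], np.cumsum(series)))
    idx = np.arange(n)
    r = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo = idx - r
    hi = idx + r + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def find_peaks_with_prominence(series: np.ndarray) -> PeakSet:
    """Locate local maxima and their topographic prominences.

    A local maximum is strictly greater than its immediate neighbours; a flat
    maximal run is represented by its middle frame (floor of the midpoint).
    Monotone or constant series yield an empty peak set.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        raise ValueError("series must have at least 3 samples")
    idx, _ = signal.find_peaks(series)
    if len(idx) == 0:
        return PeakSet(())
    prominences = signal.peak_prominences(series, idx)[0]
    heights = series[idx]
    # A peak at the global maximum stands above everything: measure it from
    # the global minimum rather than from the higher of its two side bases.
    # (The series maximum may sit on a boundary and then no peak qualifies.)
    prominences = prominences.copy()
    top = heights == float(series.max())
    prominences[top] = heights[top] - float(series.min())
    return PeakSet(tuple(
        Peak(int(i), float(h), float(p))
        for i, h, p in zip(idx, heights, prominences)
    ))


def detect_lift(trial: MotionTrial, window: int = DEFAULT_SMOOTHING_WINDOW) -> LiftWindow:
    """Detect the lift window of a single-lift trial.

    Pipeline: COM-to-hands distance -> centered moving average -> peak
    prominences -> the two most prominent peaks become the start (earlier)
    and end (later) of the lift. The returned window is half-open, so
    ``end_frame`` is one past the detected release frame.

    Raises :class:`NoLiftError` when fewer than two peaks exist (degenerate
    input such as a flat distance signal).
    """
    distance = com_hand_distance(trial)
    smoothed = moving_average(distance, window)
    peaks = find_peaks_with_prominence(smoothed)
    if len(peaks) < 2:
        raise NoLiftError(
            f"no lift found: {len(peaks)} peak(s) in the smoothed distance signal"
        )
    start, end = peaks.most_prominent(2)
    return LiftWindow.from_frames(start.frame, end.frame + 1, trial.sample_rate)


def detection_error(detected: LiftWindow, truth: LiftWindow) -> tuple[float, float]:
    """Signed start/end time errors (detected minus truth), in seconds."""
    return (
        detected.start_time - truth.start_time,
        detected.end_time - truth.end_time,
    )
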