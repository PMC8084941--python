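"""Frame-level locomotor state classification and per-phase summaries.

Female locomotion is scored from instantaneous centroid speed with fixed
bands: pausing below 4 mm/s, walking within 4–50 mm/s, and jumps above
70 mm/s (single-frame-scale spikes corresponding to take-off attempts in
an enclosed arena).  The printed bands leave (50, 70] mm/s uncovered; a
fourth state ``fast`` absorbs it — it counts toward total frames (the
pausing denominator) but never toward walking means.

Per courtship moment the summaries are: mean walking speed (sum of speed
over walking frames ÷ number of walking frames), pausing percentage
(pausing frames ÷ total phase frames × 100), and jumps per minute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, IntegrityError

STATE_PAUSE, STATE_WALK, STATE_FAST, STATE_JUMP = 0, 1, 2, 3
STATE_NAMES = ("pause", "walk", "fast", "jump")


@dataclass(frozen=True)
class SpeedThresholds:
    """Speed bands (mm/s) delimiting the locomotor states.

    pause: v < pause_max; walk: walk_min <= v <= walk_max;
    fast: walk_max < v <= jump_min; jump: v > jump_min.
    """

    pause_max: float = 4.0
    walk_min: float = 4.0
    walk_max: float = 50.0
    jump_min: float = 70.0

    def __post_init__(self) -> None:
        if not (0 < self.pause_max <= self.walk_min < self.walk_max < self.jump_min):
            raise IntegrityError(
                "thresholds must satisfy 0 < pause_max <= walk_min < walk_max < jump_min"
            )


@dataclass
class PhaseSummary:
    """Locomotor summary of one fly in one courtship moment."""

    mean_walking_speed: Optional[float]
    pausing_pct: Optional[float]
    jumps_per_min: Optional[float]
    duration_s: float
    n_frames: int
    n_walking_frames: int
    n_pause_frames: int
    n_jump_events: int


def classify_frames(speed: np.ndarray, thr: SpeedThresholds = SpeedThresholds()) -> np.ndarray:
    """Classify each frame into pause / walk / fast / jump.

    Returns an integer code array (see ``STATE_*``); exactly one state per
    frame.  Negative or non-finite speeds are an integrity error.
    """
    speed = np.asarray(speed, dtype=float)
    if not np.all(np.isfinite(speed)):
        raise IntegrityError("non-finite speed values")
    if np.any(speed < 0):
        raise IntegrityError("negative speed values")
    state = np.full(speed.shape, STATE_FAST, dtype=np.int8)
    state[speed < thr.pause_max] = STATE_PAUSE
    state[(speed >= thr.walk_min) & (speed <= thr.walk_max)] = STATE_WALK
    state[speed > thr.jump_min] = STATE_JUMP
    return state


def detect_jump_events(
    speed: np.ndarray, thr: SpeedThresholds = SpeedThresholds()
) -> np.ndarray:
    """Onset frames of jump events.

    Maximal runs of consecutive supra-threshold frames (v > jump_min)
    collapse to a single event at the run start: one take-off can span
    more than one frame at 60 Hz.
    """
    speed = np.asarray(speed, dtype=float)
    above = speed > thr.jump_min
    if not above.any():
        return np.empty(0, dtype=np.int64)
    onsets = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    return onsets


def phase_summary(
    speed: np.ndarray,
    mask: np.ndarray,
    thr: SpeedThresholds = SpeedThresholds(),
    fps: float = 60.0,
) -> PhaseSummary:
    """Summarize locomotion over the frames selected by ``mask``.

    Jump events are counted by onset frame within the phase (run-merging
    is done on the full trace first, so a jump straddling a phase edge is
    attributed to the phase containing its onset).  Empty phases yield
    all-absent metrics; a phase with no walking frames yields an absent
    walking speed, never 0.
    """
    speed = np.asarray(speed, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    duration_s = n / fps
    if n == 0:
        return PhaseSummary(None, None, None, 0.0, 0, 0, 0, 0)
    state = classify_frames(speed, thr)
    in_phase = state[mask]
    n_walk = int(np.sum(in_phase == STATE_WALK))
    n_pause = int(np.sum(in_phase == STATE_PAUSE))
    onsets = detect_jump_events(speed, thr)
    n_jumps = int(np.sum(mask[onsets])) if len(onsets) else 0
    mean_walk = (
        float(np.sum(speed[mask][in_phase == STATE_WALK]) / n_walk) if n_walk else None
    )
    return PhaseSummary(
        mean_walking_speed=mean_walk,
        pausing_pct=100.0 * n_pause / n,
        jumps_per_min=n_jumps / (duration_s / 60.0),
        duration_s=duration_s,
        n_frames=n,
        n_walking_frames=n_walk,
        n_pause_frames=n_pause,
        n_jump_events=n_jumps,
    )


def rolling_speed(
    speed: np.ndarray, fps: float, window_s: float = 15.0
) -> tuple[np.ndarray, np.ndarray]:
    """Rolling mean and SEM of raw speed over a time window.

    No speed-band filter is applied.  The window is centred and truncated
    at the trace edges.  Returns per-frame (mean, SEM) traces.
    """
    speed = np.asarray(speed, dtype=float)
    w = int(round(window_s * fps))
    if w > len(speed):
        raise InsufficientDataError("rolling window longer than trace")
    s = pd.Series(speed)
    roll = s.rolling(w, center=True, min_periods=1)
    mean = roll.mean().to_numpy()
    sem = (roll.std(ddof=1) / np.sqrt(roll.count())).to_numpy()
    sem = np.nan_to_num(sem)  # single-sample windows have zero SEM
    return mean, sem


def state_fractions(
    speed: np.ndarray, mask: np.ndarray, thr: SpeedThresholds = SpeedThresholds()
) -> dict[str, float]:
    """Percent of phase frames in each state; sums to 100 for non-empty
    phases."""
    state = classify_frames(np.asarray(speed, float), thr)[np.asarray(mask, bool)]
    n = len(state)
    if n == 0:
        return {name: float("nan") for name in STATE_NAMES}
    return {
        name: 100.0 * float(np.sum(state == code)) / n
        for code, name in enumerate(STATE_NAMES)
    }
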