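"""Looming-stimulus model and escape-response statistics.

A looming stimulus is a dark disc expanding on a screen, simulating an
object of half-size ``l`` approaching at speed ``v`` on a collision
course.  Its visual angle as a function of time-to-collision tau is

    theta(tau) = 2 * arctan((l/v) / tau)

so the stimulus is fully characterised by the size-to-speed ratio ``l/v``
(here 40 ms).  Each presentation lasts 500 ms: the disc expands for
~450 ms until it reaches a 78 degree cap, holds for ~50 ms, then
disappears.  Trials consist of a 2 min baseline followed by a 5 min
stimulation period with 7 looms at inter-stimulus intervals of 10–20 s.

Escape is quantified per loom event by the change in speed between the
0.5 s bins flanking the stimulus (delta speed), and per fly by the jump
count difference between stimulation and baseline (delta jumps).  Only
events in which the fly was walking (4–75 mm/s) both in the 0.5 s bin
before onset and in the 0.5 s bin 2.0–2.5 s after offset are included,
and frames above the 75 mm/s jump threshold are excluded from speed
averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InsufficientDataError, IntegrityError, ParameterError
from .locomotion import detect_jump_events


@dataclass(frozen=True)
class LoomingProtocol:
    """Trial structure and stimulus kinematics of the looming assay."""

    baseline_s: float = 120.0
    stimulation_s: float = 300.0
    n_looms: int = 7
    isi_min_s: float = 10.0
    isi_max_s: float = 20.0
    loom_duration_s: float = 0.5
    size_speed_ratio_s: float = 0.040  # l/v
    theta_max_deg: float = 78.0

    def __post_init__(self) -> None:
        if not (0 < self.size_speed_ratio_s):
            raise ParameterError("l/v must be positive")
        if not (0 < self.theta_max_deg < 180):
            raise ParameterError("theta_max must be in (0, 180) degrees")
        if self.n_looms and (
            self.n_looms * self.loom_duration_s
            + (self.n_looms - 1) * self.isi_min_s
            > self.stimulation_s
        ):
            raise ParameterError("looms cannot fit in the stimulation window")

    @property
    def trial_duration_s(self) -> float:
        return self.baseline_s + self.stimulation_s


@dataclass
class LoomingSchedule:
    """Sorted loom onset times (s from trial start); offsets follow at
    ``onset + loom_duration``."""

    onsets_s: np.ndarray
    loom_duration_s: float = 0.5

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if np.any(np.diff(self.onsets_s) <= 0):
            raise IntegrityError("loom onsets must be strictly increasing")

    @property
    def offsets_s(self) -> np.ndarray:
        return self.onsets_s + self.loom_duration_s

    def __len__(self) -> int:
        return len(self.onsets_s)

    def validate(self, protocol: LoomingProtocol) -> None:
        if len(self) != protocol.n_looms:
            raise IntegrityError("schedule length != protocol n_looms")
        if len(self) == 0:
            return
        stim_start, stim_end = protocol.baseline_s, protocol.trial_duration_s
        if self.onsets_s[0] < stim_start or self.offsets_s[-1] > stim_end:
            raise IntegrityError("looms outside the stimulation window")
        gaps = np.diff(self.onsets_s) - self.loom_duration_s
        if len(gaps) and (
            np.any(gaps < protocol.isi_min_s - 1e-9)
            or np.any(gaps > protocol.isi_max_s + 1e-9)
        ):
            raise IntegrityError("inter-stimulus interval outside declared range")


@dataclass(frozen=True)
class LoomResponseThresholds:
    """Speed bands and analysis bins for looming responses.

    Walking is 4–75 mm/s (strict bounds); jumps exceed 75 mm/s.  ``pre``
    and ``post`` delta-speed bins are 0.5 s; the late walking-check bin
    spans 2.0–2.5 s after loom offset.
    """

    walk_min: float = 4.0
    walk_max: float = 75.0
    jump_min: float = 75.0
    bin_s: float = 0.5
    late_bin_start_s: float = 2.0
    late_bin_end_s: float = 2.5
    walking_bin_fraction: float = 0.5  # majority rule for "walking in the bin"


# ---------------------------------------------------------------------------
# stimulus geometry
# ---------------------------------------------------------------------------

def loom_theta(time_to_collision_s, size_speed_ratio_s: float = 0.040):
    """Visual angle (degrees) of the approaching object at time-to-collision
    tau: theta = 2 * arctan((l/v) / tau).  Strictly decreasing in tau."""
    tau = np.asarray(time_to_collision_s, dtype=float)
    if np.any(tau <= 0):
        raise ParameterError("time to collision must be positive")
    theta = np.degrees(2.0 * np.arctan(size_speed_ratio_s / tau))
    return float(theta) if np.isscalar(time_to_collision_s) else theta


def theta_cap_time_s(protocol: LoomingProtocol = LoomingProtocol()) -> float:
    """Time after loom onset (s) at which the angular size first reaches the
    cap: closed form tau* = (l/v) / tan(theta_max / 2), t = duration − tau*."""
    tau_star = protocol.size_speed_ratio_s / np.tan(
        np.radians(protocol.theta_max_deg / 2.0)
    )
    return protocol.loom_duration_s - tau_star


def loom_profile(
    protocol: LoomingProtocol = LoomingProtocol(), sample_rate_hz: float = 240.0
) -> tuple[np.ndarray, np.ndarray]:
    """Angular-size time series of a single loom presentation.

    Samples presentation time s in [0, loom_duration) at the display
    refresh rate; time-to-collision is tau = duration − s and the angle is
    capped at ``theta_max_deg`` (the hold phase before the disc
    disappears).  Returns (times_s, theta_deg); the series is
    non-decreasing and its final samples equal the cap.
    """
    if sample_rate_hz <= 0:
        raise ParameterError("sample rate must be positive")
    t = np.arange(0.0, protocol.loom_duration_s, 1.0 / sample_rate_hz)
    tau = protocol.loom_duration_s - t
    theta = np.minimum(
        loom_theta(tau, protocol.size_speed_ratio_s), protocol.theta_max_deg
    )
    return t, theta


def generate_schedule(
    protocol: LoomingProtocol, seed: int | np.random.Generator
) -> LoomingSchedule:
    """Randomized loom schedule: ISIs drawn uniformly in the declared
    range, re-drawn until every offset fits inside the stimulation window.
    Deterministic per seed."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if protocol.n_looms == 0:
        return LoomingSchedule(np.empty(0), protocol.loom_duration_s)
    stim_start = protocol.baseline_s
    stim_end = protocol.trial_duration_s
    for _ in range(1000):
        # initial ISI-like delay before the first loom, then n-1 offset-to-onset ISIs
        gaps = rng.uniform(protocol.isi_min_s, protocol.isi_max_s, protocol.n_looms)
        onsets = stim_start + np.cumsum(
            np.concatenate(([gaps[0]], gaps[1:] + protocol.loom_duration_s))
        )
        if onsets[-1] + protocol.loom_duration_s <= stim_end:
            sched = LoomingSchedule(onsets, protocol.loom_duration_s)
            sched.validate(protocol)
            return sched
    raise ParameterError("could not fit a loom schedule in the stimulation window")


# ---------------------------------------------------------------------------
# response statistics
# ---------------------------------------------------------------------------

def _bin_slice(t0: float, t1: float, fps: float, n: int) -> slice:
    a, b = int(round(t0 * fps)), int(round(t1 * fps))
    if a < 0 or b > n:
        raise InsufficientDataError(f"analysis bin [{t0}, {t1}) s outside recording")
    return slice(a, b)


def _walking_in_bin(speed: np.ndarray, sl: slice, thr: LoomResponseThresholds) -> bool:
    v = speed[sl]
    if len(v) == 0:
        return False
    in_band = (v > thr.walk_min) & (v < thr.walk_max)
    return float(np.mean(in_band)) >= thr.walking_bin_fraction


def select_valid_events(
    speed: np.ndarray,
    fps: float,
    schedule: LoomingSchedule,
    thr: LoomResponseThresholds = LoomResponseThresholds(),
) -> np.ndarray:
    """Indices of loom events to include in speed analyses.

    An event is kept iff the fly was walking both in the 0.5 s bin before
    loom onset and in the 0.5 s bin from 2.0 to 2.5 s after loom offset,
    where "walking in the bin" means at least half the bin frames fall in
    the 4–75 mm/s band (the majority rule is a package choice exposed in
    :class:`LoomResponseThresholds`).
    """
    speed = np.asarray(speed, dtype=float)
    n = len(speed)
    keep = []
    for i, (onset, offset) in enumerate(zip(schedule.onsets_s, schedule.offsets_s)):
        pre = _bin_slice(onset - thr.bin_s, onset, fps, n)
        late = _bin_slice(
            offset + thr.late_bin_start_s, offset + thr.late_bin_end_s, fps, n
        )
        if _walking_in_bin(speed, pre, thr) and _walking_in_bin(speed, late, thr):
            keep.append(i)
    return np.asarray(keep, dtype=np.int64)


def triggered_profile(
    speed: np.ndarray,
    fps: float,
    schedule: LoomingSchedule,
    events: Optional[np.ndarray] = None,
    thr: LoomResponseThresholds = LoomResponseThresholds(),
    window_s: tuple[float, float] = (-2.0, 5.0),
) -> dict:
    """Event-triggered mean ± SEM speed aligned to loom onset.

    Frames with speed above the jump threshold are excluded from the
    average at their timepoint (the plots show all moments in which the
    speed was below the jump threshold).  ``events`` defaults to all
    schedule events; pass the output of :func:`select_valid_events` for
    the inclusion rule.  Returns dict with keys ``t_s``, ``mean``,
    ``sem``, ``n`` (contributing events per timepoint).
    """
    speed = np.asarray(speed, dtype=float)
    if events is None:
        events = np.arange(len(schedule))
    if len(events) == 0:
        raise InsufficientDataError("no valid looming events")
    n = len(speed)
    k0 = int(round(window_s[0] * fps))
    k1 = int(round(window_s[1] * fps))
    offsets = np.arange(k0, k1)
    rows = np.full((len(events), len(offsets)), np.nan)
    for r, i in enumerate(events):
        onset_frame = int(round(schedule.onsets_s[i] * fps))
        idx = onset_frame + offsets
        ok = (idx >= 0) & (idx < n)
        vals = speed[idx[ok]]
        vals = np.where(vals > thr.jump_min, np.nan, vals)
        rows[r, ok] = vals
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN / ddof slices
        mean = np.nanmean(rows, axis=0)
        count = np.sum(~np.isnan(rows), axis=0)
        sd = np.nanstd(rows, axis=0, ddof=1)
        sem = np.where(count > 1, sd / np.sqrt(np.maximum(count, 1)), 0.0)
    return {"t_s": offsets / fps, "mean": mean, "sem": sem, "n": count}


def delta_speed(
    speed: np.ndarray,
    fps: float,
    onset_s: float,
    offset_s: float,
    thr: LoomResponseThresholds = LoomResponseThresholds(),
) -> float:
    """Change in speed caused by one loom: mean speed in the 0.5 s bin
    after offset minus the 0.5 s bin before onset, jump frames excluded."""
    speed = np.asarray(speed, dtype=float)
    n = len(speed)
    pre = speed[_bin_slice(onset_s - thr.bin_s, onset_s, fps, n)]
    post = speed[_bin_slice(offset_s, offset_s + thr.bin_s, fps, n)]
    pre = pre[pre <= thr.jump_min]
    post = post[post <= thr.jump_min]
    if len(pre) == 0 or len(post) == 0:
        raise InsufficientDataError("delta-speed bin contains only jump frames")
    return float(np.mean(post) - np.mean(pre))


def event_delta_speeds(
    speed: np.ndarray,
    fps: float,
    schedule: LoomingSchedule,
    events: Optional[np.ndarray] = None,
    thr: LoomResponseThresholds = LoomResponseThresholds(),
) -> np.ndarray:
    """Delta speed for each (valid) loom event of one fly."""
    if events is None:
        events = np.arange(len(schedule))
    return np.array([
        delta_speed(speed, fps, schedule.onsets_s[i], schedule.offsets_s[i], thr)
        for i in events
    ])


def delta_jumps(
    speed: np.ndarray,
    fps: float,
    protocol: LoomingProtocol = LoomingProtocol(),
    thr: LoomResponseThresholds = LoomResponseThresholds(),
) -> dict:
    """Per-fly jump counts in the baseline and stimulation windows and
    their difference (stimulation − baseline).

    Jumps are run-merged events above 75 mm/s; counts are raw per-window
    counts over the protocol's fixed 2 min / 5 min windows.
    """
    speed = np.asarray(speed, dtype=float)
    # detect_jump_events only consults jump_min, so the looming thresholds
    # (75 mm/s) drop in directly
    onsets = detect_jump_events(speed, thr)
    t = onsets / fps
    base_end = protocol.baseline_s
    stim_end = protocol.trial_duration_s
    n_base = int(np.sum(t < base_end))
    n_stim = int(np.sum((t >= base_end) & (t < stim_end)))
    return {"baseline": n_base, "stimulation": n_stim, "delta": n_stim - n_base}
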