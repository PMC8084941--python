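"""Synthetic two-fly trials with known ground truth.

Each generator emits the same trajectory/annotation structures the
analysis consumes, driven by explicit behavioral parameters, so every
downstream stage (segmentation, classification, looming statistics,
epoch analysis, test dispatch) can be validated by parameter recovery
without real recordings.

The female speed trace is a per-frame mixture of pausing (speed jittered
uniformly in [0, 1) mm/s, exercising the < 4 mm/s band), walking (draws
from a phase-specific distribution clipped to the walking band) and
single-frame jump spikes drawn uniformly in (75, 120] mm/s — high enough
to clear both the courtship (70 mm/s) and looming (75 mm/s) jump
thresholds.  Positions are integrated from the speed trace along a
smoothed random heading and reflected at the arena wall, so coordinates
stay in bounds without materially altering the speed trace.

Determinism: every generator is a pure function of (params, seed); each
trial derives an independent substream from (seed, trial index), so
adding a trial never perturbs earlier trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .activation import EpochProtocol
from .courtship import CourtshipAnnotation
from .errors import ParameterError
from .looming import LoomingProtocol, LoomingSchedule, generate_schedule
from .trajectory import Arena, PairTrajectory

JUMP_SPEED_RANGE = (75.0, 120.0)  # mm/s, uniform draw (lo, hi]
PAUSE_SPEED_RANGE = (0.0, 1.0)    # mm/s, uniform draw [lo, hi)


def _trial_rng(seed: int, trial: int, stream: int = 0) -> np.random.Generator:
    """Independent substream per (seed, trial, stream)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(trial), int(stream)]))


@dataclass(frozen=True)
class PhaseProfile:
    """Female locomotor statistics during one courtship moment."""

    walk_speed_mean: float   # mm/s
    walk_speed_sd: float = 2.0
    pause_prob: float = 0.3  # per frame
    jump_rate_per_min: float = 0.0

    def __post_init__(self) -> None:
        if self.walk_speed_mean < 0 or self.walk_speed_sd < 0:
            raise ParameterError("walk speed parameters must be >= 0")
        if not 0 <= self.pause_prob <= 1:
            raise ParameterError("pause_prob must be in [0, 1]")
        if self.jump_rate_per_min < 0:
            raise ParameterError("jump rate must be >= 0")


#: Control females slow down and pause more once courtship starts, with
#: essentially no jumping.
CONTROL_PROFILES = {
    "before": PhaseProfile(walk_speed_mean=11.0, pause_prob=0.30),
    "on": PhaseProfile(walk_speed_mean=7.0, pause_prob=0.45),
    "off": PhaseProfile(walk_speed_mean=8.0, pause_prob=0.50),
}

#: Escape phenotype: acute speed-up, reduced pausing, and ~2 jumps/min
#: during courtship bouts, returning toward baseline between bouts.
SILENCED_PROFILES = {
    "before": PhaseProfile(walk_speed_mean=11.0, pause_prob=0.30),
    "on": PhaseProfile(walk_speed_mean=17.0, pause_prob=0.12, jump_rate_per_min=2.0),
    "off": PhaseProfile(walk_speed_mean=11.0, pause_prob=0.35,
                        jump_rate_per_min=0.3),
}


@dataclass
class CourtshipSimParams:
    """Conditions of a simulated courtship trial (40 mm circular arena,
    60 Hz recording, up to 10 min analysed from courtship onset)."""

    fps: float = 60.0
    duration_s: float = 660.0
    latency_to_court_mean_s: float = 45.0
    bout_len_mean_s: float = 15.0
    bout_gap_mean_s: float = 10.0
    n_bouts: Optional[int] = None          # None: fill the recording
    profiles: dict = field(default_factory=lambda: dict(CONTROL_PROFILES))
    male_court_distance_mean_mm: float = 3.0
    male_court_distance_sd_mm: float = 0.8
    copulation: bool = False
    copulation_latency_mean_s: float = 300.0
    arena: Arena = field(default_factory=Arena)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("before", "on", "off"):
            if name not in self.profiles:
                raise ParameterError(f"missing phase profile {name!r}")
        if self.bout_len_mean_s <= 0 or self.bout_gap_mean_s <= 0:
            raise ParameterError("bout model means must be positive")


@dataclass
class LoomSimParams:
    """Conditions of a simulated looming trial: single female, 30 mm
    arena, 2 min baseline + 5 min stimulation at 60 Hz.  The response
    kernel is a speed dip during the loom followed by a locomotion surge
    after loom offset."""

    fps: float = 60.0
    protocol: LoomingProtocol = field(default_factory=LoomingProtocol)
    baseline_speed_mean: float = 10.0  # mm/s, inside the 4-75 walking band
    baseline_speed_sd: float = 1.5
    dip_depth: float = 6.0             # mm/s subtracted during the loom
    dip_duration_s: float = 0.5
    surge_amplitude: float = 15.0      # mm/s added after loom offset
    surge_duration_s: float = 1.5
    jump_prob_per_loom: float = 0.0
    arena: Arena = field(default_factory=lambda: Arena(diameter_mm=30.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.jump_prob_per_loom <= 1:
            raise ParameterError("jump probability must be in [0, 1]")
        min_isi = self.protocol.isi_min_s
        if self.dip_duration_s + self.surge_duration_s >= min_isi:
            raise ParameterError("response kernel longer than the minimum ISI")


@dataclass
class ActivationSimParams:
    """Conditions of a simulated optogenetic activation trial: courting
    pair, 3/3/3 min epochs at 60 Hz, raw-speed epoch means."""

    fps: float = 60.0
    protocol: EpochProtocol = field(default_factory=EpochProtocol)
    epoch_speed_means: tuple[float, float, float] = (12.0, 2.0, 11.0)
    speed_sd: float = 1.5
    copulation_prob_by_epoch: tuple[float, float, float] = (0.0, 0.0, 0.0)
    arena: Arena = field(default_factory=Arena)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epoch_speed_means) < 0:
            raise ParameterError("epoch speed means must be >= 0")


@dataclass
class GroundTruth:
    """Generator-side record of what was simulated, for recovery tests."""

    bouts: list[tuple[int, int]] = field(default_factory=list)
    phase_walk_speed_means: dict = field(default_factory=dict)
    jump_frames: list[int] = field(default_factory=list)
    copulation_frame: Optional[int] = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# position integration
# ---------------------------------------------------------------------------

def _integrate_positions(
    speed: np.ndarray, fps: float, arena: Arena, rng: np.random.Generator,
    heading_sd: float = 0.25,
) -> np.ndarray:
    """Integrate a speed trace into in-bounds positions along a smoothed
    random heading.

    A step that would leave the arena is re-aimed toward the arena centre
    (with a little angular noise) instead — the step length, hence the
    speed trace recovered by differencing, is preserved exactly.
    """
    import math

    n = len(speed)
    radius = arena.diameter_mm / 2.0 - 1.0  # keep the centroid off the wall
    xy = np.empty((n, 2))
    x, y = rng.uniform(-radius / 2, radius / 2, size=2)
    heading = float(rng.uniform(0, 2 * np.pi))
    steps = speed / fps
    turns = rng.normal(0.0, heading_sd, size=n)
    noise = rng.normal(0.0, 0.3, size=n)
    xy[0] = (x, y)
    r2max = radius * radius
    for k in range(1, n):
        heading += turns[k]
        s = steps[k]
        nx = x + s * math.cos(heading)
        ny = y + s * math.sin(heading)
        if nx * nx + ny * ny > r2max:
            heading = math.atan2(-y, -x) + noise[k]
            nx = x + s * math.cos(heading)
            ny = y + s * math.sin(heading)
            if nx * nx + ny * ny > r2max:  # noisy re-aim still exits: go straight in
                heading = math.atan2(-y, -x)
                nx = x + s * math.cos(heading)
                ny = y + s * math.sin(heading)
        x, y = nx, ny
        xy[k] = (x, y)
    return xy


def _speed_trace(
    n: int, phase_of_frame: np.ndarray, profiles: dict,
    fps: float, rng: np.random.Generator,
    walk_band: tuple[float, float] = (4.0, 50.0),
) -> tuple[np.ndarray, list[int]]:
    """Per-frame mixture of pause / walk / jump given a phase label per
    frame (indices into the ordered profile list; -1 = outside any
    analysed phase, treated as 'off')."""
    names = list(profiles)
    speed = np.empty(n)
    jump_frames: list[int] = []
    pause_draw = rng.uniform(*PAUSE_SPEED_RANGE, size=n)
    walk_draws = {
        name: np.clip(
            rng.normal(prof.walk_speed_mean, prof.walk_speed_sd, size=n),
            walk_band[0], walk_band[1],
        )
        for name, prof in profiles.items()
    }
    u_pause = rng.uniform(size=n)
    u_jump = rng.uniform(size=n)
    jump_speed = rng.uniform(JUMP_SPEED_RANGE[0], JUMP_SPEED_RANGE[1], size=n)
    jump_speed = np.nextafter(jump_speed, np.inf)  # (lo, hi]: exclude lo
    for idx, name in enumerate(names):
        prof = profiles[name]
        mask = phase_of_frame == idx
        speed[mask] = np.where(
            u_pause[mask] < prof.pause_prob, pause_draw[mask], walk_draws[name][mask]
        )
        p_jump = prof.jump_rate_per_min / (60.0 * fps)
        jmask = mask & (u_jump < p_jump)
        speed[jmask] = jump_speed[jmask]
        jump_frames.extend(np.flatnonzero(jmask).tolist())
    return speed, sorted(jump_frames)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _gen_bouts(params: CourtshipSimParams, rng: np.random.Generator,
               n_frames: int) -> tuple[list[tuple[int, int]], int]:
    fps = params.fps
    latency = rng.exponential(params.latency_to_court_mean_s)
    latency = float(np.clip(latency, 5.0, 120.0))
    start = int(round(latency * fps))
    bouts = []
    cursor = start
    count = 0
    while cursor < n_frames - 1:
        if params.n_bouts is not None and count >= params.n_bouts:
            break
        length = max(2.0, rng.exponential(params.bout_len_mean_s))
        end = min(n_frames, cursor + int(round(length * fps)))
        if end - cursor < 1:
            break
        bouts.append((cursor, end))
        count += 1
        gap = max(1.0, rng.exponential(params.bout_gap_mean_s))
        cursor = end + int(round(gap * fps))
    if not bouts:
        raise ParameterError("bout model produced no bouts within the recording")
    if bouts[-1][1] > n_frames:
        raise ParameterError("bout total exceeds recording duration")
    return bouts, start


def gen_courtship_trial(
    params: CourtshipSimParams, trial: int = 0
) -> tuple[PairTrajectory, CourtshipAnnotation, GroundTruth]:
    """Simulate one courting pair.

    The annotation's bouts equal the ground-truth bouts by construction.
    During bouts the male tracks the female at a pursuit distance well
    below the 5.5 mm courtship distance; between bouts he wanders at
    larger separations.
    """
    rng = _trial_rng(params.seed, trial)
    n = int(round(params.duration_s * params.fps))
    bouts, court_start = _gen_bouts(params, rng, n)

    copulation = None
    if params.copulation:
        lat = rng.exponential(params.copulation_latency_mean_s)
        cop = court_start + int(round(lat * params.fps))
        if cop < n:
            copulation = max(cop, bouts[0][0])

    # phase of each frame: before / on / off
    on_mask = np.zeros(n, dtype=bool)
    for s, e in bouts:
        on_mask[s:e] = True
    phase = np.full(n, 2)                 # off
    phase[:court_start] = 0               # before
    phase[on_mask] = 1                    # on
    profiles = {"before": params.profiles["before"], "on": params.profiles["on"],
                "off": params.profiles["off"]}
    speed, jump_frames = _speed_trace(n, phase, profiles, params.fps, rng)

    female = _integrate_positions(speed, params.fps, params.arena, rng)

    # male: pursue during bouts, wander between
    d_court = np.clip(
        rng.normal(params.male_court_distance_mean_mm,
                   params.male_court_distance_sd_mm, size=n),
        0.5, 5.4,
    )
    d_far = rng.uniform(6.5, 15.0, size=n)
    dist = np.where(on_mask, d_court, d_far)
    # place the male on the female's centre-ward side (plus noise) so he
    # stays inside the arena
    to_centre = np.arctan2(-female[:, 1], -female[:, 0])
    ang = to_centre + rng.normal(0.0, 0.4, size=n)
    male = female + dist[:, None] * np.column_stack([np.cos(ang), np.sin(ang)])
    radius = params.arena.diameter_mm / 2.0 - 0.5
    r = np.hypot(male[:, 0], male[:, 1])
    over = r > radius
    male[over] *= (radius / r[over])[:, None]

    traj = PairTrajectory(np.arange(n), params.fps, female, male, params.arena)
    ann = CourtshipAnnotation(bouts, n, copulation)
    truth = GroundTruth(
        bouts=bouts,
        phase_walk_speed_means={k: v.walk_speed_mean for k, v in profiles.items()},
        jump_frames=jump_frames,
        copulation_frame=copulation,
        params={"kind": "courtship", "seed": params.seed, "trial": trial},
    )
    return traj, ann, truth


def gen_loom_trial(
    params: LoomSimParams,
    schedule: Optional[LoomingSchedule] = None,
    trial: int = 0,
) -> tuple[PairTrajectory, GroundTruth]:
    """Simulate one single-fly looming trial.

    The baseline walking-speed trace receives, at each loom onset, a dip
    of ``dip_depth`` for ``dip_duration_s`` followed by a surge of
    ``surge_amplitude`` for ``surge_duration_s`` from loom offset, plus a
    single jump spike per loom with probability ``jump_prob_per_loom``
    (placed just after loom offset).
    """
    rng = _trial_rng(params.seed, trial)
    protocol = params.protocol
    if schedule is None:
        schedule = generate_schedule(protocol, _trial_rng(params.seed, trial, 1))
    fps = params.fps
    n = int(round(protocol.trial_duration_s * fps))
    speed = np.clip(
        rng.normal(params.baseline_speed_mean, params.baseline_speed_sd, size=n),
        4.5, 74.0,
    )
    jump_frames: list[int] = []
    for onset, offset in zip(schedule.onsets_s, schedule.offsets_s):
        k_on = int(round(onset * fps))
        k_off = int(round(offset * fps))
        k_dip_end = min(n, k_on + int(round(params.dip_duration_s * fps)))
        k_surge_end = k_off + int(round(params.surge_duration_s * fps))
        if k_surge_end > n:
            raise ParameterError("response kernel overruns the trial end")
        speed[k_on:k_dip_end] = np.maximum(
            speed[k_on:k_dip_end] - params.dip_depth, 0.2
        )
        speed[k_off:k_surge_end] += params.surge_amplitude
        if rng.uniform() < params.jump_prob_per_loom:
            k_jump = k_off + int(round(0.1 * fps))
            speed[k_jump] = np.nextafter(
                rng.uniform(*JUMP_SPEED_RANGE), np.inf
            )
            jump_frames.append(k_jump)

    female = _integrate_positions(speed, fps, params.arena, rng)
    traj = PairTrajectory(np.arange(n), fps, female, None, params.arena)
    truth = GroundTruth(
        jump_frames=jump_frames,
        params={"kind": "looming", "seed": params.seed, "trial": trial,
                "onsets_s": [float(t) for t in schedule.onsets_s],
                "surge_amplitude": params.surge_amplitude,
                "dip_depth": params.dip_depth},
    )
    return traj, truth


def gen_activation_trial(
    params: ActivationSimParams, trial: int = 0
) -> tuple[PairTrajectory, CourtshipAnnotation, GroundTruth]:
    """Simulate one optogenetic activation trial.

    Recording starts at courtship onset, so the annotation is a single
    bout spanning the video; the raw female speed has epoch-specific
    means.  Copulation, when drawn, occurs uniformly within its epoch.
    """
    rng = _trial_rng(params.seed, trial)
    fps = params.fps
    protocol = params.protocol
    n = int(round(protocol.trial_duration_s * fps))
    edges = np.cumsum((0.0,) + protocol.durations)
    speed = np.empty(n)
    for mean, a, b in zip(params.epoch_speed_means, edges[:-1], edges[1:]):
        ka, kb = int(round(a * fps)), int(round(b * fps))
        if mean == 0.0:
            speed[ka:kb] = 0.0
        else:
            # gamma draws: non-negative with the declared mean exactly
            shape = (mean / params.speed_sd) ** 2
            speed[ka:kb] = rng.gamma(shape, mean / shape, size=kb - ka)

    copulation = None
    for prob, a, b in zip(params.copulation_prob_by_epoch, edges[:-1], edges[1:]):
        if rng.uniform() < prob:
            copulation = int(round(rng.uniform(a, b) * fps))
            break
    if copulation is not None:
        n_kept = copulation  # video ends at copulation
        speed = speed[:max(n_kept, 2)]
        n = len(speed)

    female = _integrate_positions(speed, fps, params.arena, rng)
    dist = np.clip(rng.normal(3.0, 0.8, size=n), 0.5, 5.4)
    ang = np.arctan2(-female[:, 1], -female[:, 0]) + rng.normal(0, 0.4, size=n)
    male = female + dist[:, None] * np.column_stack([np.cos(ang), np.sin(ang)])
    radius = params.arena.diameter_mm / 2.0 - 0.5
    r = np.hypot(male[:, 0], male[:, 1])
    over = r > radius
    male[over] *= (radius / r[over])[:, None]

    traj = PairTrajectory(np.arange(n), fps, female, male, params.arena)
    ann = CourtshipAnnotation([(0, n)], n, copulation if copulation and copulation < n
                              else copulation)
    truth = GroundTruth(
        bouts=[(0, n)],
        copulation_frame=copulation,
        params={"kind": "activation", "seed": params.seed, "trial": trial,
                "epoch_speed_means": list(params.epoch_speed_means)},
    )
    return traj, ann, truth
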