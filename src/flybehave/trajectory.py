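"""Data model and I/O for tracked fly trajectories.

A trial is a time-indexed table of centroid positions for a female fly and
(optionally) a male fly, recorded at a fixed frame rate in a circular or
rectangular arena.  All positions are in millimetres, all times in seconds,
all speeds in mm/s; pixel-to-mm calibration is the responsibility of
whoever writes the track table.

Frame indexing is 0-based and all frame intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InsufficientDataError, IntegrityError

#: columns of the track-table dialect, in file order
PAIR_COLUMNS = ["frame", "t_s", "female_x_mm", "female_y_mm", "male_x_mm", "male_y_mm"]
SINGLE_COLUMNS = ["frame", "t_s", "female_x_mm", "female_y_mm"]

#: default tolerance (mm) for coordinates slightly outside the arena,
#: accounting for centroid jitter at the wall
ARENA_TOLERANCE_MM = 1.0


@dataclass(frozen=True)
class Arena:
    """Arena geometry; ``circle`` uses ``diameter_mm``, ``rect`` uses
    ``width_mm`` × ``height_mm``."""

    shape: str = "circle"
    diameter_mm: float = 40.0
    width_mm: Optional[float] = None
    height_mm: Optional[float] = None

    def contains(self, xy: np.ndarray, tol: float = ARENA_TOLERANCE_MM) -> np.ndarray:
        """Boolean mask of points inside the arena (± tolerance).

        Coordinates are centred on the arena centre.
        """
        xy = np.asarray(xy, dtype=float)
        if self.shape == "circle":
            r = np.hypot(xy[..., 0], xy[..., 1])
            return r <= self.diameter_mm / 2.0 + tol
        half_w = (self.width_mm or 0.0) / 2.0 + tol
        half_h = (self.height_mm or 0.0) / 2.0 + tol
        return (np.abs(xy[..., 0]) <= half_w) & (np.abs(xy[..., 1]) <= half_h)

    def to_dict(self) -> dict:
        d = {"shape": self.shape}
        if self.shape == "circle":
            d["diameter_mm"] = float(self.diameter_mm)
        else:
            d["width_mm"] = float(self.width_mm)
            d["height_mm"] = float(self.height_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Arena":
        return cls(
            shape=d.get("shape", "circle"),
            diameter_mm=float(d.get("diameter_mm", 40.0)),
            width_mm=d.get("width_mm"),
            height_mm=d.get("height_mm"),
        )


@dataclass
class PairTrajectory:
    """Two-fly (or single-female) centroid trajectory.

    Attributes
    ----------
    frame : (n,) int array, 0-based, contiguous
    fps : frames per second (60 for tracked assays, 25 for the
        receptivity-only videos)
    female, male : (n, 2) float arrays of x/y centroids in mm; ``male`` is
        None for single-fly assays (e.g. looming trials)
    arena : arena geometry
    interpolated : (n,) bool mask of frames whose coordinates were filled
        by interpolation rather than tracked (never silently dropped)
    """

    frame: np.ndarray
    fps: float
    female: np.ndarray
    male: Optional[np.ndarray] = None
    arena: Arena = field(default_factory=Arena)
    interpolated: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.female = np.asarray(self.female, dtype=float).reshape(-1, 2) \
            if self.n_frames else np.empty((0, 2))
        if self.male is not None:
            self.male = np.asarray(self.male, dtype=float).reshape(-1, 2) \
                if self.n_frames else np.empty((0, 2))
        if self.interpolated is None:
            self.interpolated = np.zeros(self.n_frames, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.frame)

    @property
    def time(self) -> np.ndarray:
        """Time of each frame in seconds (= frame / fps)."""
        return self.frame / self.fps

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def is_pair(self) -> bool:
        return self.male is not None

    def validate(self, arena_tol: float = ARENA_TOLERANCE_MM) -> None:
        """Raise :class:`IntegrityError` on contract violations."""
        n = self.n_frames
        if n and not np.array_equal(self.frame, self.frame[0] + np.arange(n)):
            raise IntegrityError("frame index is not contiguous")
        if self.female.shape != (n, 2):
            raise IntegrityError("female coordinate shape mismatch")
        if not np.all(np.isfinite(self.female)):
            raise IntegrityError("non-finite female coordinates")
        if self.male is not None:
            if self.male.shape != (n, 2):
                raise IntegrityError("male coordinate shape mismatch")
            if not np.all(np.isfinite(self.male)):
                raise IntegrityError("non-finite male coordinates")
        if self.fps <= 0:
            raise IntegrityError("fps must be positive")
        for name, xy in (("female", self.female), ("male", self.male)):
            if xy is None or not len(xy):
                continue
            inside = self.arena.contains(xy, tol=arena_tol)
            if not inside.all():
                k = int(np.flatnonzero(~inside)[0])
                raise IntegrityError(
                    f"{name} coordinate outside arena at frame {k}: {xy[k]}"
                )


@dataclass
class KinematicSeries:
    """Per-frame kinematics derived from a :class:`PairTrajectory`.

    ``speed_*`` are instantaneous centroid speeds (mm/s); ``distance`` is
    centroid-to-centroid inter-fly distance (mm), None for single-fly
    trajectories.  Lengths equal the trajectory length.
    """

    speed_female: np.ndarray
    speed_male: Optional[np.ndarray]
    distance: Optional[np.ndarray]
    fps: float

    def __len__(self) -> int:
        return len(self.speed_female)


def _speed(xy: np.ndarray, fps: float) -> np.ndarray:
    """Backward-difference speed; speed[0] := speed[1] (first displacement
    is undefined, the tracker's convention is unknowable from its output)."""
    disp = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
    v = np.empty(len(xy))
    v[1:] = disp * fps
    v[0] = v[1]
    return v


def _smooth(xy: np.ndarray, window_frames: int) -> np.ndarray:
    out = np.column_stack([
        pd.Series(xy[:, i]).rolling(window_frames, center=True, min_periods=1).mean()
        for i in (0, 1)
    ])
    return out


def compute_kinematics(
    traj: PairTrajectory, smoothing_s: Optional[float] = None
) -> KinematicSeries:
    """Compute per-frame speeds and inter-fly distance.

    Speeds are raw frame-to-frame displacements × fps by default, because
    every threshold rule downstream (pausing, walking, jumping) is applied
    to raw, un-binned instantaneous speed.  ``smoothing_s`` optionally
    applies a centred moving average to the positions before
    differentiation.

    Raises
    ------
    InsufficientDataError
        for trajectories with fewer than 2 frames.
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("need >= 2 frames to compute speed")
    fxy, mxy = traj.female, traj.male
    if smoothing_s:
        w = max(1, int(round(smoothing_s * traj.fps)))
        fxy = _smooth(fxy, w)
        mxy = _smooth(mxy, w) if mxy is not None else None
    speed_f = _speed(fxy, traj.fps)
    speed_m = _speed(mxy, traj.fps) if mxy is not None else None
    dist = (
        np.hypot(fxy[:, 0] - mxy[:, 0], fxy[:, 1] - mxy[:, 1])
        if mxy is not None
        else None
    )
    return KinematicSeries(speed_f, speed_m, dist, traj.fps)


# ---------------------------------------------------------------------------
# track-table I/O
#
# Delimited text (tab) with YAML metadata on leading comment lines:
#   # fps: 60
#   # arena: {shape: circle, diameter_mm: 40.0}
#   frame  t_s  female_x_mm  female_y_mm  male_x_mm  male_y_mm
# ---------------------------------------------------------------------------

MAX_INTERP_GAP = 2  # frames; longer gaps are an integrity error in strict mode


def _read_header_meta(path: Path) -> dict:
    lines = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            lines.append(line.lstrip("#").rstrip("\n"))
    meta = yaml.safe_load("\n".join(lines)) if lines else None
    return meta or {}


def read_tracks(
    path, dialect: str = "pair", strict: bool = True
) -> tuple[PairTrajectory, int]:
    """Read a track table.

    Parameters
    ----------
    path : file path
    dialect : "pair" (female + male columns required) or "single"
        (female only, e.g. looming assays)
    strict : if True, frame gaps longer than :data:`MAX_INTERP_GAP` raise
        :class:`IntegrityError`; if False they are interpolated and flagged.

    Returns
    -------
    (trajectory, n_interpolated_frames)
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such track file: {path}")
    meta = _read_header_meta(path)
    if "fps" not in meta:
        raise FormatError("track header must declare fps")
    fps = float(meta["fps"])
    arena = Arena.from_dict(meta.get("arena", {}))

    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    want = PAIR_COLUMNS if dialect == "pair" else SINGLE_COLUMNS
    missing = [c for c in want if c not in df.columns]
    if missing:
        raise FormatError(f"track table missing columns: {missing}")

    if len(df) == 0:
        return PairTrajectory(np.empty(0, int), fps, np.empty((0, 2)),
                              np.empty((0, 2)) if dialect == "pair" else None,
                              arena), 0

    frames = df["frame"].to_numpy(np.int64)
    if np.any(np.diff(frames) <= 0):
        raise FormatError("frame column must be strictly increasing")
    gaps = np.diff(frames) - 1
    if strict and np.any(gaps > MAX_INTERP_GAP):
        raise IntegrityError(
            f"frame gap of {int(gaps.max())} frames exceeds "
            f"tolerance of {MAX_INTERP_GAP}"
        )

    full = np.arange(frames[0], frames[-1] + 1)
    n_interp = int(len(full) - len(frames))
    coord_cols = want[2:]
    if n_interp:
        df = df.set_index("frame").reindex(full)
        df[coord_cols] = df[coord_cols].interpolate(method="index")
        interp_mask = df[coord_cols[0]].isna().to_numpy() | ~np.isin(full, frames)
        df = df.reset_index()
    else:
        interp_mask = np.zeros(len(full), dtype=bool)

    female = df[["female_x_mm", "female_y_mm"]].to_numpy(float)
    male = (
        df[["male_x_mm", "male_y_mm"]].to_numpy(float) if dialect == "pair" else None
    )
    traj = PairTrajectory(full, fps, female, male, arena, interpolated=interp_mask)
    traj.validate()
    return traj, n_interp


def write_tracks(traj: PairTrajectory, path) -> Path:
    """Write a track table re-readable by :func:`read_tracks` with
    identical content (lossless for finite values)."""
    path = Path(path)
    meta = {"fps": float(traj.fps), "arena": traj.arena.to_dict()}
    cols = {"frame": traj.frame, "t_s": traj.time,
            "female_x_mm": traj.female[:, 0], "female_y_mm": traj.female[:, 1]}
    if traj.male is not None:
        cols["male_x_mm"] = traj.male[:, 0]
        cols["male_y_mm"] = traj.male[:, 1]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        for line in yaml.safe_dump(meta, sort_keys=False).splitlines():
            fh.write(f"# {line}\n")
        # repr-precision floats make the round trip bit-exact
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return path


def rigid_transform(traj: PairTrajectory, angle_rad: float,
                    shift_mm: tuple[float, float]) -> PairTrajectory:
    """Globally rotate then translate all coordinates (speeds and
    distances are invariant under this map). Arena validation is not
    re-applied: the transform is a test/analysis utility."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[c, -s], [s, c]])
    female = traj.female @ rot.T + shift_mm
    male = traj.male @ rot.T + shift_mm if traj.male is not None else None
    return replace(traj, female=female, male=male)
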