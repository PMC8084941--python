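"""Epoch analysis of the optogenetic activation assay.

Trials follow a fixed protocol: 3 min baseline with the activation light
off, 3 min light on, 3 min light off again, recording starting at
courtship onset (the camera is only started once the male courts).  Speed
here means raw centroid speed with no band filter — pausing and jump
frames are included, unlike the walking-speed metric of the courtship
assay.  The headline quantities are per-fly differences in mean speed
between epochs (activation − baseline, lightsOFF − baseline) and the
assignment of copulation events to epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .courtship import CourtshipAnnotation
from .errors import InsufficientDataError, ParameterError

EPOCH_NAMES = ("baseline", "activation", "lights_off")


@dataclass(frozen=True)
class EpochProtocol:
    """Contiguous epoch durations (s) from trial start."""

    baseline_s: float = 180.0
    activation_s: float = 180.0
    lights_off_s: float = 180.0

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.activation_s, self.lights_off_s) <= 0:
            raise ParameterError("epoch durations must be positive")

    @property
    def durations(self) -> tuple[float, float, float]:
        return (self.baseline_s, self.activation_s, self.lights_off_s)

    @property
    def trial_duration_s(self) -> float:
        return sum(self.durations)

    def epoch_of_time(self, t_s: float) -> Optional[str]:
        """Epoch containing time ``t_s`` (half-open boundaries), or None
        past the protocol end."""
        edges = np.cumsum((0.0,) + self.durations)
        for name, a, b in zip(EPOCH_NAMES, edges[:-1], edges[1:]):
            if a <= t_s < b:
                return name
        return None


def epoch_masks(
    protocol: EpochProtocol, n_frames: int, fps: float,
    copulation_frame: Optional[int] = None,
) -> tuple[dict[str, np.ndarray], bool]:
    """Boolean frame masks for the three epochs.

    Masks are contiguous and half-open, truncated at copulation and at
    video end; returns ``(masks, truncated)`` where ``truncated`` flags
    any truncation.  A trial shorter than the baseline epoch cannot be
    analyzed.
    """
    end = n_frames if copulation_frame is None else min(copulation_frame, n_frames)
    edges_s = np.cumsum((0.0,) + protocol.durations)
    edges = [int(round(e * fps)) for e in edges_s]
    if end < edges[1]:
        raise InsufficientDataError("trial shorter than the baseline epoch")
    masks = {}
    truncated = end < edges[-1]
    for name, a, b in zip(EPOCH_NAMES, edges[:-1], edges[1:]):
        m = np.zeros(n_frames, dtype=bool)
        m[a:min(b, end)] = True
        masks[name] = m
    return masks, truncated


def epoch_speed_deltas(
    speed: np.ndarray, masks: dict[str, np.ndarray]
) -> dict[str, Optional[float]]:
    """Per-fly epoch mean raw speeds and their deltas.

    Returns mean speed per epoch plus ``activation_minus_baseline`` and
    ``lights_off_minus_baseline``; deltas involving an empty epoch are
    absent (None).  No speed-band filtering is applied.
    """
    speed = np.asarray(speed, dtype=float)
    means: dict[str, Optional[float]] = {}
    for name in EPOCH_NAMES:
        m = masks[name]
        means[name] = float(np.mean(speed[m])) if m.any() else None
    out: dict[str, Optional[float]] = dict(means)
    for delta_name, epoch in (
        ("activation_minus_baseline", "activation"),
        ("lights_off_minus_baseline", "lights_off"),
    ):
        if means[epoch] is None or means["baseline"] is None:
            out[delta_name] = None
        else:
            out[delta_name] = means[epoch] - means["baseline"]
    return out


def copulation_latency_by_epoch(
    annotations: Iterable[CourtshipAnnotation],
    fps: float,
    protocol: EpochProtocol = EpochProtocol(),
) -> dict[str, dict]:
    """Assign each copulation to the epoch containing its frame.

    Returns per-epoch ``{"count", "latencies_s"}`` where latencies are
    copulation times (s from trial start = courtship onset, since
    recording starts when the male courts).
    """
    out = {name: {"count": 0, "latencies_s": []} for name in EPOCH_NAMES}
    for ann in annotations:
        if ann.copulation_frame is None:
            continue
        t = ann.copulation_frame / fps
        epoch = protocol.epoch_of_time(t)
        if epoch is not None:
            out[epoch]["count"] += 1
            out[epoch]["latencies_s"].append(t)
    return out
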