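"""Courtship-phase segmentation and trial-level courtship metrics.

Courtship happens in bouts: the male orients to, follows, and sings to the
female intermittently.  Female locomotion is therefore quantified in three
moments of the courtship dynamic:

* **before** — from the start of recording to the first courtship frame;
* **courtship ON** — frames inside courtship bouts;
* **courtship OFF** — frames between bouts, after courtship has started.

Analysis covers the first 10 minutes of courtship or until copulation,
whichever comes first.  Trials with a courtship index below 20% are
excluded.  When males do not court at all (e.g. mutant males that lack the
courtship program), inter-fly distance below 5.5 mm serves as a proxy for
courtship, since close proximity almost always coincides with courtship.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError
from .trajectory import KinematicSeries

#: inclusion threshold on the courtship index
MIN_COURTSHIP_INDEX = 0.20
#: analysis window length from the first courtship frame
ANALYSIS_WINDOW_MIN = 10.0
#: inter-fly distance (mm) below which courtship is highly likely
COURTSHIP_DISTANCE_MM = 5.5


@dataclass
class CourtshipAnnotation:
    """Courtship bout intervals plus optional copulation time.

    ``bouts`` are half-open frame intervals ``[start, end)``, sorted and
    non-overlapping.  ``copulation_frame`` is the onset of copulation, if
    it occurred; ``n_frames`` is the video end.
    """

    bouts: list[tuple[int, int]]
    n_frames: int
    copulation_frame: Optional[int] = None

    def __post_init__(self) -> None:
        self.bouts = [(int(s), int(e)) for s, e in self.bouts]
        for s, e in self.bouts:
            if e - s < 1:
                raise IntegrityError(f"bout [{s}, {e}) shorter than 1 frame")
        for (s0, e0), (s1, e1) in zip(self.bouts, self.bouts[1:]):
            if s1 < e0:
                raise IntegrityError("bouts overlap or are unsorted")
        if self.copulation_frame is not None:
            self.copulation_frame = int(self.copulation_frame)
            if self.bouts and self.copulation_frame < self.bouts[0][0]:
                raise IntegrityError("copulation precedes first courtship bout")

    @property
    def has_courtship(self) -> bool:
        return len(self.bouts) > 0

    @property
    def courtship_start(self) -> Optional[int]:
        return self.bouts[0][0] if self.bouts else None


@dataclass
class PhaseMasks:
    """Boolean frame masks for the three courtship moments.

    Masks are mutually exclusive; ``before | on | off`` covers exactly
    ``[0, window_end)`` where ``window`` is the half-open analysis window
    ``[courtship start, window end)``.
    """

    before: np.ndarray
    on: np.ndarray
    off: np.ndarray
    window: tuple[int, int]

    def phase(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class ProximityMasks:
    """Distance-proxy analogue of :class:`PhaseMasks` for non-courting
    males: ``near`` = inter-fly distance strictly below the courtship
    distance, ``far`` = complement."""

    near: np.ndarray
    far: np.ndarray
    threshold_mm: float = COURTSHIP_DISTANCE_MM


def segment_phases(
    ann: CourtshipAnnotation,
    n_frames: int,
    fps: float,
    window_min: float = ANALYSIS_WINDOW_MIN,
) -> PhaseMasks:
    """Segment a trial into before / courtship ON / courtship OFF.

    The analysis window runs from the first courtship frame for
    ``window_min`` minutes, truncated at copulation and at video end.
    With no bouts, ``before`` covers the whole video and ON/OFF are empty
    (the no-courtship signal is ``ann.has_courtship``).
    """
    if n_frames < ann.n_frames:
        raise IntegrityError("n_frames shorter than the annotated video end")
    before = np.zeros(n_frames, dtype=bool)
    on = np.zeros(n_frames, dtype=bool)
    off = np.zeros(n_frames, dtype=bool)
    if not ann.has_courtship:
        before[:] = True
        return PhaseMasks(before, on, off, window=(n_frames, n_frames))

    start = ann.courtship_start
    end = start + int(round(window_min * 60.0 * fps))
    if ann.copulation_frame is not None:
        end = min(end, ann.copulation_frame)
    end = min(end, n_frames)

    before[:start] = True
    for s, e in ann.bouts:
        on[max(s, start):min(e, end)] = True
    window_mask = np.zeros(n_frames, dtype=bool)
    window_mask[start:end] = True
    off[:] = window_mask & ~on
    return PhaseMasks(before, on, off, window=(start, end))


def courtship_index(ann: CourtshipAnnotation) -> float:
    """Fraction of frames with courtship from the first courtship frame to
    the end of the video (ending at copulation when one occurred, since no
    courtship is scored after copulation)."""
    if not ann.has_courtship:
        raise IntegrityError("courtship index undefined without bouts")
    start = ann.courtship_start
    end = ann.n_frames if ann.copulation_frame is None else ann.copulation_frame
    denom = end - start
    if denom <= 0:
        return 1.0  # copulation at courtship onset: degenerate, fully courting
    courting = sum(min(e, end) - max(s, start) for s, e in ann.bouts
                   if min(e, end) > max(s, start))
    return courting / denom


def latencies(ann: CourtshipAnnotation, fps: float) -> dict:
    """Latency to court (from recording start) and latency to copulation
    (from the beginning of male courtship), in seconds; absent keys map to
    None."""
    out = {"latency_to_court_s": None, "latency_to_copulation_s": None}
    if ann.has_courtship:
        out["latency_to_court_s"] = ann.courtship_start / fps
        if ann.copulation_frame is not None:
            out["latency_to_copulation_s"] = (
                ann.copulation_frame - ann.courtship_start
            ) / fps
    return out


def apply_inclusion_filter(
    trials: Iterable, min_ci: float = MIN_COURTSHIP_INDEX
) -> tuple[list, list[tuple[object, str]]]:
    """Keep trials whose courtship index is >= ``min_ci`` (boundary
    inclusive) and that have at least one bout.

    ``trials`` yields objects with a ``.annotation`` attribute or bare
    :class:`CourtshipAnnotation` instances.  Returns ``(kept, dropped)``
    where each dropped entry carries a machine-readable reason.
    """
    kept, dropped = [], []
    for trial in trials:
        ann = trial.annotation if hasattr(trial, "annotation") else trial
        if not ann.has_courtship:
            dropped.append((trial, "no_courtship"))
            continue
        ci = courtship_index(ann)
        if ci < min_ci:
            dropped.append((trial, f"courtship_index_below_threshold:{ci:.3f}"))
            continue
        kept.append(trial)
    return kept, dropped


def distance_proxy_masks(
    kin: KinematicSeries, threshold_mm: float = COURTSHIP_DISTANCE_MM
) -> ProximityMasks:
    """Courtship-distance proxy masks: ``near`` where inter-fly distance is
    strictly below the threshold (ties go to ``far``)."""
    if kin.distance is None:
        raise IntegrityError("distance proxy requires a two-fly trajectory")
    near = kin.distance < threshold_mm
    return ProximityMasks(near=near, far=~near, threshold_mm=threshold_mm)


# ---------------------------------------------------------------------------
# annotation-table I/O: delimited text, columns kind / start_frame /
# end_frame, where kind is "bout" (end required) or "copulation" (end empty)
# ---------------------------------------------------------------------------

def read_annotations(path, n_frames: int) -> CourtshipAnnotation:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such annotation file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("kind", "start_frame"):
        if col not in df.columns:
            raise FormatError(f"annotation table missing column {col!r}")
    bouts = []
    copulation = None
    for _, row in df.iterrows():
        if row["kind"] == "bout":
            bouts.append((int(row["start_frame"]), int(row["end_frame"])))
        elif row["kind"] == "copulation":
            copulation = int(row["start_frame"])
        else:
            raise FormatError(f"unknown annotation kind {row['kind']!r}")
    return CourtshipAnnotation(sorted(bouts), n_frames, copulation)


def write_annotations(ann: CourtshipAnnotation, path) -> Path:
    path = Path(path)
    rows = [{"kind": "bout", "start_frame": s, "end_frame": e}
            for s, e in ann.bouts]
    if ann.copulation_frame is not None:
        rows.append({"kind": "copulation", "start_frame": ann.copulation_frame,
                     "end_frame": ""})
    pd.DataFrame(rows, columns=["kind", "start_frame", "end_frame"]).to_csv(
        path, sep="\t", index=False
    )
    return path
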