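"""Orchestration: simulate trial batches to disk and analyze them back
into tidy summary tables and statistical reports.

File layout of a simulated batch (all plain text)::

    out/
      manifest.yaml                 # resolved config, seed, trial list
      trial_000.tracks.tsv          # track table (+ YAML header)
      trial_000.annot.tsv           # bout/copulation annotation
      trial_000.truth.yaml          # generator ground truth

Analysis commands read a batch directory, apply the inclusion rules, and
write summary tables (one row per fly × phase/epoch/event), a dropped-
trials report with machine-readable reasons, and per-comparison
statistical reports.  Identical (inputs, config, seed) produce identical
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import activation as act
from . import courtship as ct
from . import locomotion as loco
from . import looming as loom
from . import synthetic as syn
from .config import RunConfig
from .errors import FormatError
from .stats import GroupedData, compare_groups, zero_median_reference_test
from .trajectory import compute_kinematics, read_tracks, write_tracks

log = logging.getLogger("flybehave")

PHASES = ("before", "on", "off")


def _trial_name(i: int) -> str:
    return f"trial_{i:03d}"


def simulate_batch(
    kind: str, n_trials: int, seed: int, outdir,
    condition: str = "control", config: Optional[RunConfig] = None,
) -> Path:
    """Simulate ``n_trials`` trials of ``kind`` (courtship | looming |
    activation) into ``outdir`` and write a manifest."""
    config = config or RunConfig(seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials = []
    for i in range(n_trials):
        name = _trial_name(i)
        if kind == "courtship":
            profiles = (syn.SILENCED_PROFILES if condition == "silenced"
                        else syn.CONTROL_PROFILES)
            params = syn.CourtshipSimParams(seed=seed, profiles=dict(profiles))
            traj, ann, truth = syn.gen_courtship_trial(params, trial=i)
            ct.write_annotations(ann, outdir / f"{name}.annot.tsv")
        elif kind == "looming":
            params = syn.LoomSimParams(seed=seed)
            traj, truth = syn.gen_loom_trial(params, trial=i)
        elif kind == "activation":
            params = syn.ActivationSimParams(seed=seed)
            traj, ann, truth = syn.gen_activation_trial(params, trial=i)
            ct.write_annotations(ann, outdir / f"{name}.annot.tsv")
        else:
            raise FormatError(f"unknown simulation kind {kind!r}")
        write_tracks(traj, outdir / f"{name}.tracks.tsv")
        with open(outdir / f"{name}.truth.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(truth), fh, sort_keys=False)
        trials.append(name)
        log.info("simulated %s %s", kind, name)
    manifest = {"kind": kind, "condition": condition, "n_trials": n_trials,
                "seed": seed, "trials": trials,
                "config": config.to_dict(), "config_digest": config.digest}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir


def _batch_trials(indir: Path) -> list[str]:
    manifest = yaml.safe_load((indir / "manifest.yaml").read_text())
    return manifest["trials"]


def analyze_courtship(indir, outdir, config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Per-phase locomotor summaries for a courtship batch.

    Applies the courtship-index inclusion filter, segments phases within
    the 10-min-or-copulation window, and writes ``summaries.tsv`` (one
    row per trial × phase), ``dropped.tsv`` and the resolved config.
    """
    config = config or RunConfig()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, dropped = [], []
    names = _batch_trials(indir)
    for name in names:
        traj, _ = read_tracks(indir / f"{name}.tracks.tsv")
        ann = ct.read_annotations(indir / f"{name}.annot.tsv", traj.n_frames)
        kept, drop = ct.apply_inclusion_filter([ann], config.min_courtship_index)
        if not kept:
            dropped.append({"trial": name, "reason": drop[0][1]})
            continue
        kin = compute_kinematics(traj)
        masks = ct.segment_phases(ann, traj.n_frames, traj.fps,
                                  config.analysis_window_min)
        for phase in PHASES:
            s = loco.phase_summary(kin.speed_female, masks.phase(phase),
                                   config.speed_thresholds, traj.fps)
            rows.append({"trial": name, "phase": phase,
                         "mean_walking_speed_mm_s": s.mean_walking_speed,
                         "pausing_pct": s.pausing_pct,
                         "jumps_per_min": s.jumps_per_min,
                         "duration_s": s.duration_s,
                         "n_frames": s.n_frames,
                         "courtship_index": ct.courtship_index(ann)})
    log.info("courtship analysis: %d/%d trials kept", len(names) - len(dropped),
             len(names))
    summaries = pd.DataFrame(rows)
    summaries.to_csv(outdir / "summaries.tsv", sep="\t", index=False)
    pd.DataFrame(dropped, columns=["trial", "reason"]).to_csv(
        outdir / "dropped.tsv", sep="\t", index=False
    )
    config.to_yaml(outdir / "config.yaml")
    return summaries


def analyze_looming(indir, outdir, config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Looming-response tables: per-event delta speed (valid events only)
    and per-fly baseline/stimulation/delta jump counts."""
    config = config or RunConfig()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr, protocol = config.loom_thresholds, config.looming_protocol
    event_rows, fly_rows = [], []
    for name in _batch_trials(indir):
        traj, _ = read_tracks(indir / f"{name}.tracks.tsv", dialect="single")
        truth = yaml.safe_load((indir / f"{name}.truth.yaml").read_text())
        schedule = loom.LoomingSchedule(np.asarray(truth["params"]["onsets_s"]),
                                        protocol.loom_duration_s)
        kin = compute_kinematics(traj)
        speed = kin.speed_female
        valid = loom.select_valid_events(speed, traj.fps, schedule, thr)
        deltas = loom.event_delta_speeds(speed, traj.fps, schedule, valid, thr)
        for i, d in zip(valid, deltas):
            event_rows.append({"trial": name, "event": int(i),
                               "delta_speed_mm_s": float(d)})
        jumps = loom.delta_jumps(speed, traj.fps, protocol, thr)
        fly_rows.append({"trial": name, "n_valid_events": len(valid), **jumps})
    events = pd.DataFrame(event_rows,
                          columns=["trial", "event", "delta_speed_mm_s"])
    flies = pd.DataFrame(fly_rows)
    events.to_csv(outdir / "delta_speed.tsv", sep="\t", index=False)
    flies.to_csv(outdir / "jumps.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "config.yaml")
    log.info("looming analysis: %d flies, %d valid events", len(flies), len(events))
    return events


def analyze_activation(indir, outdir, config: Optional[RunConfig] = None
                       ) -> pd.DataFrame:
    """Epoch mean speeds and deltas per fly, plus the zero-median
    reference test on the lightsOFF − baseline deltas."""
    config = config or RunConfig()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    protocol = config.epoch_protocol
    rows = []
    annotations = []
    for name in _batch_trials(indir):
        traj, _ = read_tracks(indir / f"{name}.tracks.tsv")
        ann = ct.read_annotations(indir / f"{name}.annot.tsv", traj.n_frames)
        annotations.append(ann)
        kin = compute_kinematics(traj)
        masks, truncated = act.epoch_masks(protocol, traj.n_frames, traj.fps,
                                           ann.copulation_frame)
        deltas = act.epoch_speed_deltas(kin.speed_female, masks)
        rows.append({"trial": name, "truncated": truncated, **deltas})
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "epoch_speed.tsv", sep="\t", index=False)
    off_deltas = table["lights_off_minus_baseline"].dropna().to_numpy()
    if len(off_deltas) >= 5:
        report = zero_median_reference_test(off_deltas, seed=config.seed,
                                            alpha=config.alpha)
        report.to_yaml(outdir / "lights_off_vs_reference.yaml")
    cop = act.copulation_latency_by_epoch(annotations, config.fps, protocol)
    with open(outdir / "copulation_by_epoch.yaml", "w") as fh:
        yaml.safe_dump(cop, fh, sort_keys=False)
    config.to_yaml(outdir / "config.yaml")
    return table


def compare_summary_groups(
    tables: dict[str, pd.DataFrame], metric: str, phase: str = "on",
    design: str = "independent", alpha: float = 0.05,
):
    """Dispatch the decision tree on one per-phase metric across labelled
    batches (e.g. control vs silenced ON-phase walking speed)."""
    groups = {}
    for label, df in tables.items():
        sel = df[df["phase"] == phase][metric].dropna().to_numpy()
        groups[label] = sel
    return compare_groups(GroupedData(groups, design=design), alpha=alpha)
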