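"""Run configuration: every analysis threshold and protocol in one
serializable object, defaulting to the assays' standard values, with per-run
YAML overrides.  Every pipeline run echoes its fully resolved config (and
a hash of it) so inclusion rules and thresholds are auditable."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .activation import EpochProtocol
from .courtship import ANALYSIS_WINDOW_MIN, COURTSHIP_DISTANCE_MM, MIN_COURTSHIP_INDEX
from .errors import FormatError
from .locomotion import SpeedThresholds
from .looming import LoomResponseThresholds, LoomingProtocol


@dataclass
class RunConfig:
    speed_thresholds: SpeedThresholds = field(default_factory=SpeedThresholds)
    loom_thresholds: LoomResponseThresholds = field(
        default_factory=LoomResponseThresholds
    )
    looming_protocol: LoomingProtocol = field(default_factory=LoomingProtocol)
    epoch_protocol: EpochProtocol = field(default_factory=EpochProtocol)
    min_courtship_index: float = MIN_COURTSHIP_INDEX
    courtship_distance_mm: float = COURTSHIP_DISTANCE_MM
    analysis_window_min: float = ANALYSIS_WINDOW_MIN
    alpha: float = 0.05
    seed: int = 0
    fps: float = 60.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        nested = {
            "speed_thresholds": SpeedThresholds,
            "loom_thresholds": LoomResponseThresholds,
            "looming_protocol": LoomingProtocol,
            "epoch_protocol": EpochProtocol,
        }
        for key, typ in nested.items():
            if key in d:
                kwargs[key] = typ(**d.pop(key))
        known = {f.name for f in dataclasses.fields(cls)}
        for key, value in d.items():
            if key not in known:
                raise FormatError(f"unknown config field: {key}")
            kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
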