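"""Experiment configuration: defaults, validation and YAML/JSON loading."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .autobleed import HemorrhageProtocol
from .subject import SubjectSpec
from .trace import ValidationError

DEFAULT_TARGET_CAP = 65.0  # mmHg: target = min(baseline, 65)


class ConfigError(ValueError):
    pass


def resolve_target(baseline_map: float, cap: float = DEFAULT_TARGET_CAP) -> float:
    """Resuscitation target rule: the pre-hemorrhage baseline or the
    damage-control cap of 65 mmHg, whichever is lower."""
    return float(min(baseline_map, cap))


@dataclass
class ExperimentConfig:
    """Everything needed to run one simulated protocol end to end."""

    controller_kind: str = "ARC"  # "ARC" | "DFL"
    target_map: Optional[float] = None  # mmHg; None -> min(baseline, 65)
    control_period: float = 15.0  # s
    nibp_period: float = 60.0  # s
    resus_duration_min: float = 60.0
    stabilization_min: float = 5.0
    wb_cap: float = 1000.0  # mL of whole blood before switching to LR
    max_rate: float = 250.0  # mL/min
    seed: int = 0
    input_source: str = "upsampled"  # "upsampled" | "intermittent" | "continuous"
    death_map: float = 20.0  # mmHg floor
    death_min: float = 5.0  # sustained minutes at/below floor -> flagged
    subject: SubjectSpec = field(default_factory=SubjectSpec)
    protocol: HemorrhageProtocol = field(default_factory=HemorrhageProtocol)
    arc_params: dict = field(default_factory=dict)  # pace/window/floor/cap overrides
    dfl_params: dict = field(default_factory=dict)  # bolus flag, partitions, rules

    def validate(self) -> None:
        if self.controller_kind not in ("ARC", "DFL"):
            raise ConfigError(f"unknown controller_kind {self.controller_kind!r}")
        if self.control_period <= 0 or self.nibp_period <= 0:
            raise ConfigError("periods must be > 0")
        n = self.nibp_period / self.control_period
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("control_period must divide nibp_period")
        if self.target_map is not None and self.target_map <= 0:
            raise ConfigError("target_map must be > 0")
        if self.wb_cap < 0:
            raise ConfigError("wb_cap must be >= 0")
        if self.max_rate <= 0:
            raise ConfigError("max_rate must be > 0")
        if self.input_source not in ("upsampled", "intermittent", "continuous"):
            raise ConfigError(f"unknown input_source {self.input_source!r}")
        self.subject.validate()
        self.protocol.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "subject" in d and isinstance(d["subject"], dict):
            sub = dict(d["subject"])
            for key in ("baseline_range", "slope_range"):
                if key in sub:
                    sub[key] = tuple(sub[key])
            d["subject"] = SubjectSpec(**sub)
        if "protocol" in d and isinstance(d["protocol"], dict):
            proto = dict(d["protocol"])
            if "step_targets" in proto:
                proto["step_targets"] = tuple(proto["step_targets"])
            d["protocol"] = HemorrhageProtocol(**proto)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config(path) -> ExperimentConfig:
    """Load a YAML or JSON experiment config, filling defaults.

    If the subject specification pins the baseline (zero-width range) and
    no explicit target is given, the target is resolved immediately as
    min(baseline, 65 mmHg); otherwise it is resolved at run time from the
    measured post-stabilization baseline.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg = ExperimentConfig.from_dict(raw)
    lo, hi = cfg.subject.baseline_range
    if cfg.target_map is None and lo == hi:
        cfg.target_map = resolve_target(lo)
    return cfg
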