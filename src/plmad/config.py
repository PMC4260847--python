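"""Pipeline configuration: defaults, YAML/JSON loading and validation.

Every default equals the corresponding published scoring constant; all of
them can be overridden from a YAML (or JSON) config file whose nested keys
mirror the dataclass fields, e.g.::

    detector:
      rms_window_s: 0.15
    snr_plus:
      enabled: true
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detect import DetectorRules

__all__ = [
    "AdaptiveConfig",
    "ThresholdConfig",
    "SnrPlusConfig",
    "RespiratoryConfig",
    "PLMRulesConfig",
    "PeriodicityConfig",
    "HRConfig",
    "PipelineConfig",
    "load_config",
]


@dataclass(frozen=True)
class AdaptiveConfig:
    mode: str = "auto"  # auto | ecg | self | off
    n_weights: int = 5
    forgetting: float = 0.999
    init_delta: float = 100.0
    self_ref_advance: int = 5

    def __post_init__(self):
        if self.mode not in ("auto", "ecg", "self", "off"):
            raise ValueError(f"adaptive.mode must be auto|ecg|self|off, got {self.mode!r}")


@dataclass(frozen=True)
class ThresholdConfig:
    U_uv: float = 8.0
    L_uv: float = 2.0
    noise_window_s: float = 20.0
    shutoff_uv: float = 50.0

    def __post_init__(self):
        if not (self.U_uv > self.L_uv > 0):
            raise ValueError("need U_uv > L_uv > 0")


@dataclass(frozen=True)
class SnrPlusConfig:
    enabled: bool = False
    gate_uv: float = 2.0


@dataclass(frozen=True)
class RespiratoryConfig:
    mode: str = "splmad"  # splmad | aasm2007 | off
    window: tuple = (5.0, 0.5, 0.5, 5.0)  # pre-onset, post-onset, pre-offset, post-offset
    overlap: str = "interval"  # interval | onset

    def __post_init__(self):
        if self.mode not in ("splmad", "aasm2007", "off"):
            raise ValueError(f"respiratory.mode must be splmad|aasm2007|off, got {self.mode!r}")
        if len(self.window) != 4:
            raise ValueError("respiratory.window needs 4 components")


@dataclass(frozen=True)
class PLMRulesConfig:
    imi_min_s: float = 5.0
    imi_max_s: float = 90.0
    min_run: int = 4
    short_imi: str = "break"  # break | ignore


@dataclass(frozen=True)
class PeriodicityConfig:
    imi_min_s: float = 10.0
    imi_max_s: float = 90.0
    min_seq: int = 3


@dataclass(frozen=True)
class HRConfig:
    n_cycles: int = 10


@dataclass
class PipelineConfig:
    adaptive: AdaptiveConfig = field(default_factory=AdaptiveConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    snr_plus: SnrPlusConfig = field(default_factory=SnrPlusConfig)
    detector: DetectorRules = field(default_factory=DetectorRules)
    respiratory: RespiratoryConfig = field(default_factory=RespiratoryConfig)
    plm: PLMRulesConfig = field(default_factory=PLMRulesConfig)
    periodicity: PeriodicityConfig = field(default_factory=PeriodicityConfig)
    hr: HRConfig = field(default_factory=HRConfig)
    merge_rule: str = "mean"  # mean | sum | max

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {
            "adaptive": AdaptiveConfig,
            "thresholds": ThresholdConfig,
            "snr_plus": SnrPlusConfig,
            "detector": DetectorRules,
            "respiratory": RespiratoryConfig,
            "plm": PLMRulesConfig,
            "periodicity": PeriodicityConfig,
            "hr": HRConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sections:
                if not isinstance(value, dict):
                    raise ValueError(f"config section {key!r} must be a mapping")
                names = {f.name for f in dataclasses.fields(sections[key])}
                unknown = set(value) - names
                if unknown:
                    raise ValueError(
                        f"unknown keys in config section {key!r}: {sorted(unknown)}"
                    )
                if key == "respiratory" and "window" in value:
                    value = {**value, "window": tuple(value["window"])}
                kwargs[key] = sections[key](**value)
            elif key == "merge_rule":
                kwargs[key] = value
            else:
                raise ValueError(f"unknown top-level config key {key!r}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path) -> None:
        """Echo the effective configuration to a YAML file."""
        data = self.to_dict()
        data["respiratory"]["window"] = list(data["respiratory"]["window"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from YAML (JSON accepted as a subset)."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return PipelineConfig.from_dict(data)
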