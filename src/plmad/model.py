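"""Shared domain types for the leg-movement detection pipeline.

Conventions used throughout the package:

* all time coordinates are float seconds from recording start;
* all intervals are half-open ``[onset, offset)``;
* sample indices are 0-based;
* amplitudes are microvolts (uV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np

__all__ = [
    "SignalTrace",
    "Recording",
    "Hypnogram",
    "RespEvent",
    "LMEvent",
    "SubjectMetrics",
    "LM_FLAGS",
    "SLEEP_STAGES",
    "STAGE_VOCAB",
    "normalize_stage",
]

#: Flags an LMEvent may carry.  ``bridged``/``merged`` are informational;
#: the remaining flags mark the event as rejected at some pipeline stage.
LM_FLAGS = frozenset(
    {
        "bridged",
        "merged",
        "too_short",
        "too_long",
        "auc_rejected",
        "resp_excluded",
        "detector_off",
        "open_ended",
    }
)

REJECT_FLAGS = frozenset({"too_short", "too_long", "auc_rejected", "resp_excluded", "detector_off"})

#: Internal stage vocabulary (R&K with REM collapsed to ``R``).
STAGE_VOCAB = ("W", "S1", "S2", "S3", "S4", "R", "UNSCORED")
SLEEP_STAGES = frozenset({"S1", "S2", "S3", "S4", "R"})

# Accepts both R&K (S1..S4) and AASM (N1..N3) tokens; N3 maps onto S3.
_STAGE_ALIASES: Mapping[str, str] = {
    "W": "W",
    "WAKE": "W",
    "0": "W",
    "S1": "S1",
    "N1": "S1",
    "1": "S1",
    "S2": "S2",
    "N2": "S2",
    "2": "S2",
    "S3": "S3",
    "N3": "S3",
    "3": "S3",
    "S4": "S4",
    "4": "S4",
    "R": "R",
    "REM": "R",
    "5": "R",
    "UNSCORED": "UNSCORED",
    "U": "UNSCORED",
    "?": "UNSCORED",
    "7": "UNSCORED",
}


def normalize_stage(token: str) -> str:
    """Map an R&K or AASM stage token onto the internal vocabulary.

    Raises ``ValueError`` for tokens outside the vocabulary.
    """
    key = str(token).strip().upper()
    try:
        return _STAGE_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown sleep stage token {token!r}; expected one of "
            f"{sorted(set(_STAGE_ALIASES))}"
        ) from None


@dataclass
class SignalTrace:
    """A uniformly sampled single-channel signal in microvolts."""

    samples: np.ndarray
    fs: float
    label: str = ""
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"trace {self.label!r} contains non-finite samples")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def time_to_index(self, t: float) -> int:
        return int(round((t - self.start_time) * self.fs))

    def index_to_time(self, i: int) -> float:
        return self.start_time + i / self.fs

    def copy_with(self, samples: np.ndarray, label: Optional[str] = None) -> "SignalTrace":
        return SignalTrace(
            samples=np.asarray(samples, dtype=np.float64),
            fs=self.fs,
            label=self.label if label is None else label,
            start_time=self.start_time,
        )


@dataclass
class Recording:
    """A set of named traces sharing a common time origin."""

    traces: dict[str, SignalTrace]
    duration_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("recording must contain at least one trace")
        if self.duration_s <= 0:
            self.duration_s = max(t.duration_s for t in self.traces.values())

    def __getitem__(self, label: str) -> SignalTrace:
        return self.traces[label]

    def __contains__(self, label: str) -> bool:
        return label in self.traces

    @property
    def labels(self) -> list[str]:
        return list(self.traces)


@dataclass
class Hypnogram:
    """Sleep-stage sequence in fixed-length epochs (30 s by default)."""

    stages: list[str]
    epoch_len_s: float = 30.0

    def __post_init__(self) -> None:
        if self.epoch_len_s <= 0:
            raise ValueError("epoch length must be positive")
        self.stages = [normalize_stage(s) for s in self.stages]

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return len(self.stages) * self.epoch_len_s

    def stage_at(self, t: float) -> str:
        """Stage of the epoch containing time ``t``; UNSCORED beyond coverage."""
        if t < 0:
            return "UNSCORED"
        idx = int(t // self.epoch_len_s)
        if idx >= len(self.stages):
            return "UNSCORED"
        return self.stages[idx]

    def is_sleep_at(self, t: float) -> bool:
        return self.stage_at(t) in SLEEP_STAGES

    def total_sleep_s(self, span_s: Optional[float] = None) -> float:
        return self._stage_seconds(SLEEP_STAGES, span_s)

    def total_wake_s(self, span_s: Optional[float] = None) -> float:
        return self._stage_seconds({"W"}, span_s)

    def _stage_seconds(self, stages: Iterable[str], span_s: Optional[float]) -> float:
        stages = set(stages)
        total = 0.0
        for i, st in enumerate(self.stages):
            start = i * self.epoch_len_s
            if span_s is not None and start >= span_s:
                break
            dur = self.epoch_len_s
            if span_s is not None:
                dur = min(dur, span_s - start)
            if st in stages:
                total += dur
        return total


@dataclass(frozen=True)
class RespEvent:
    """A scored respiratory event (apnea/hypopnea) interval."""

    onset_s: float
    offset_s: float
    type: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.onset_s < self.offset_s):
            raise ValueError(
                f"respiratory event must satisfy 0 <= onset < offset, got "
                f"[{self.onset_s}, {self.offset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class LMEvent:
    """A detected leg-movement interval with audit provenance flags."""

    onset_s: float
    offset_s: float
    peak_rms_uv: float = 0.0
    auc_norm_uv: float = 0.0
    state: str = "UNSCORED"
    flags: set = field(default_factory=set)
    run_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.onset_s >= self.offset_s:
            raise ValueError(f"empty LM interval [{self.onset_s}, {self.offset_s})")
        unknown = set(self.flags) - LM_FLAGS
        if unknown:
            raise ValueError(f"unknown LM flags: {sorted(unknown)}")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def retained(self) -> bool:
        """True when the event survived every rejection stage."""
        return not (set(self.flags) & REJECT_FLAGS)

    def with_flags(self, *flags: str) -> "LMEvent":
        return replace(self, flags=set(self.flags) | set(flags))


@dataclass
class SubjectMetrics:
    """Subject-level summary indices.

    Undefined quantities (e.g. night ratio when one half of the night has no
    events) are ``None``, never 0 or infinity.
    """

    plms_per_h: Optional[float] = None
    plmw_per_h: Optional[float] = None
    lm_count: int = 0
    plm_count: int = 0
    periodicity_sleep: Optional[float] = None
    periodicity_wake: Optional[float] = None
    night_ratio_plm: Optional[float] = None
    night_ratio_lm: Optional[float] = None
    hr_delta_mean: Optional[float] = None
    hr_slope_mean: Optional[float] = None
    hours_sleep: float = 0.0
    hours_wake: float = 0.0
    reliable: bool = True

    def __post_init__(self) -> None:
        if self.lm_count < 0 or self.plm_count < 0:
            raise ValueError("counts must be non-negative")
        for name in ("periodicity_sleep", "periodicity_wake"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def to_dict(self) -> dict:
        return {
            "plms_per_h": self.plms_per_h,
            "plmw_per_h": self.plmw_per_h,
            "lm_count": self.lm_count,
            "plm_count": self.plm_count,
            "periodicity_sleep": self.periodicity_sleep,
            "periodicity_wake": self.periodicity_wake,
            "night_ratio_plm": self.night_ratio_plm,
            "night_ratio_lm": self.night_ratio_lm,
            "hr_delta_mean": self.hr_delta_mean,
            "hr_slope_mean": self.hr_slope_mean,
            "hours_sleep": self.hours_sleep,
            "hours_wake": self.hours_wake,
            "reliable": self.reliable,
        }
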