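"""End-to-end detection pipeline binding all stages together."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .config import PipelineConfig
from .context import ExclusionWindows, respiratory_exclude
from .detect import detect_lm
from .io import write_results
from .metrics import PLMRun, compute_subject_metrics, detect_r_peaks, find_plm_runs
from .model import Hypnogram, LMEvent, Recording, RespEvent, SubjectMetrics

__all__ = ["PipelineResult", "run_detection"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    events: list[LMEvent]  # every second-pass candidate, flags included
    retained: list[LMEvent]  # events surviving all rejection stages
    runs: list[PLMRun]
    metrics: SubjectMetrics
    stage_counts: dict = field(default_factory=dict)


def run_detection(
    recording: Recording,
    hypnogram: Hypnogram,
    resp_events: Sequence[RespEvent] = (),
    config: Optional[PipelineConfig] = None,
    out_dir=None,
) -> PipelineResult:
    """Detect LMs, apply respiratory exclusion, classify PLM runs and
    compute subject metrics; optionally write result files to ``out_dir``."""
    cfg = config or PipelineConfig()

    events = detect_lm(recording, hypnogram, cfg)

    win = ExclusionWindows(*cfg.respiratory.window)
    events = respiratory_exclude(
        events, list(resp_events), win, mode=cfg.respiratory.mode,
        overlap=cfg.respiratory.overlap,
    )

    retained = [ev for ev in events if ev.retained]
    runs = find_plm_runs(
        retained,
        imi_min_s=cfg.plm.imi_min_s,
        imi_max_s=cfg.plm.imi_max_s,
        min_run=cfg.plm.min_run,
        short_imi=cfg.plm.short_imi,
    )

    r_peaks = None
    if "ecg" in recording:
        r_peaks = detect_r_peaks(recording["ecg"])

    metrics = compute_subject_metrics(
        retained,
        runs,
        hypnogram,
        study_span_s=recording.duration_s,
        r_peaks=r_peaks,
        hr_n_cycles=cfg.hr.n_cycles,
        periodicity_kw={
            "imi_min_s": cfg.periodicity.imi_min_s,
            "imi_max_s": cfg.periodicity.imi_max_s,
            "min_seq": cfg.periodicity.min_seq,
        },
    )

    counts = {
        "candidates": len(events),
        "retained": len(retained),
        "too_short": sum(1 for e in events if "too_short" in e.flags),
        "too_long": sum(1 for e in events if "too_long" in e.flags),
        "auc_rejected": sum(1 for e in events if "auc_rejected" in e.flags),
        "resp_excluded": sum(
            1
            for e in events
            if "resp_excluded" in e.flags
            and not (set(e.flags) & {"too_short", "too_long", "auc_rejected"})
        ),
        "detector_off": sum(
            1 for e in events if set(e.flags) == {"detector_off"}
        ),
        "plm": metrics.plm_count,
        "runs": len(runs),
    }
    log.info("pipeline stage counts: %s", counts)

    if out_dir is not None:
        out_dir = Path(out_dir)
        write_results(events, metrics, out_dir)
        cfg.dump(out_dir / "config_effective.yaml")
        with open(out_dir / "run_log.txt", "w") as fh:
            for key, value in counts.items():
                fh.write(f"{key}: {value}\n")

    return PipelineResult(
        events=events,
        retained=retained,
        runs=runs,
        metrics=metrics,
        stage_counts=counts,
    )
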