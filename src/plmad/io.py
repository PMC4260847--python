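"""Readers and writers for recordings, annotations and result files."""

from __future__ import annotations

import csv
import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.signal import resample_poly

from . import edf
from .model import Hypnogram, LMEvent, Recording, RespEvent, SignalTrace, SubjectMetrics

__all__ = [
    "ChannelNotFoundError",
    "read_recording",
    "merge_leg_channels",
    "resample_trace",
    "read_hypnogram",
    "read_resp_events",
    "write_results",
    "read_lm_events",
]

log = logging.getLogger(__name__)


class ChannelNotFoundError(KeyError):
    def __init__(self, requested: str, available: Sequence[str]):
        super().__init__(
            f"channel {requested!r} not found; available channels: {sorted(available)}"
        )
        self.requested = requested
        self.available = list(available)


def read_recording(path, channel_map: Optional[dict[str, str]] = None) -> Recording:
    """Read an EDF file, optionally renaming channels via ``channel_map``.

    ``channel_map`` maps role names (e.g. ``"leg_left"``) to EDF channel
    labels.  Every requested label must exist; a missing one raises
    :class:`ChannelNotFoundError` listing the available labels.
    """
    rec = edf.read_edf(path)
    if channel_map is None:
        return rec
    traces = {}
    for role, label in channel_map.items():
        if label not in rec.traces:
            raise ChannelNotFoundError(label, rec.labels)
        traces[role] = rec.traces[label]
    return Recording(traces=traces, duration_s=rec.duration_s, meta=rec.meta)


def merge_leg_channels(
    left: SignalTrace, right: SignalTrace, rule: str = "mean"
) -> SignalTrace:
    """Combine the two leg-EMG channels into a single trace.

    ``rule``: ``mean`` (default, per-sample average), ``sum`` or ``max``
    (per-sample max of the rectified signals).  Lengths may differ by at
    most one sample (the longer trace is truncated).
    """
    if left.fs != right.fs:
        raise ValueError(
            f"leg channels have different sampling rates ({left.fs} vs "
            f"{right.fs} Hz); resample one with resample_trace() first"
        )
    if abs(len(left) - len(right)) > 1:
        raise ValueError(
            f"leg channel length mismatch: {len(left)} vs {len(right)} samples"
        )
    n = min(len(left), len(right))
    a, b = left.samples[:n], right.samples[:n]
    if rule == "mean":
        merged = 0.5 * (a + b)
    elif rule == "sum":
        merged = a + b
    elif rule == "max":
        merged = np.maximum(np.abs(a), np.abs(b))
    else:
        raise ValueError(f"unknown merge rule {rule!r}; use mean|sum|max")
    return SignalTrace(samples=merged, fs=left.fs, label="LEG", start_time=left.start_time)


def resample_trace(trace: SignalTrace, fs_target: float) -> SignalTrace:
    """Polyphase-resample a trace to ``fs_target``."""
    if trace.fs == fs_target:
        return trace
    from fractions import Fraction

    frac = Fraction(fs_target / trace.fs).limit_denominator(1000)
    out = resample_poly(trace.samples, frac.numerator, frac.denominator)
    return SignalTrace(
        samples=out, fs=fs_target, label=trace.label, start_time=trace.start_time
    )


def read_hypnogram(path, epoch_len_s: float = 30.0) -> Hypnogram:
    """Read a hypnogram CSV with columns ``epoch_index,stage``."""
    stages: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().lower() in ("epoch_index", "epoch"):
                continue
            stages.append((int(row[0]), row[1].strip()))
    stages.sort(key=lambda r: r[0])
    return Hypnogram(stages=[s for _, s in stages], epoch_len_s=epoch_len_s)


def read_resp_events(path) -> list[RespEvent]:
    """Read a respiratory-event CSV with columns ``onset_s,offset_s,type``."""
    events: list[RespEvent] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().lower() in ("onset_s", "onset"):
                continue
            etype = row[2].strip().lower() if len(row) > 2 and row[2].strip() else "other"
            events.append(RespEvent(float(row[0]), float(row[1]), etype))
    events.sort(key=lambda e: (e.onset_s, e.offset_s))
    for prev, cur in zip(events, events[1:]):
        if cur.onset_s < prev.offset_s:
            warnings.warn(
                f"overlapping respiratory events [{prev.onset_s},{prev.offset_s}) "
                f"and [{cur.onset_s},{cur.offset_s}); kept as-is",
                stacklevel=2,
            )
    return events


_LM_COLUMNS = ["onset_s", "offset_s", "duration_s", "state", "flags", "run_id"]


def write_results(
    events: Sequence[LMEvent],
    metrics: Optional[SubjectMetrics],
    out_dir,
) -> dict[str, Path]:
    """Write ``lm_events.csv`` and ``metrics.json`` into ``out_dir``.

    Output is bit-stable for fixed inputs (fixed column order, sorted flags,
    repr-based float formatting).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    ev_path = out_dir / "lm_events.csv"
    with open(ev_path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_LM_COLUMNS)
        for ev in events:
            writer.writerow(
                [
                    repr(float(ev.onset_s)),
                    repr(float(ev.offset_s)),
                    repr(float(ev.duration_s)),
                    ev.state,
                    "|".join(sorted(ev.flags)),
                    "" if ev.run_id is None else ev.run_id,
                ]
            )
    paths["lm_events"] = ev_path

    if metrics is not None:
        m_path = out_dir / "metrics.json"
        with open(m_path, "w") as fh:
            json.dump(metrics.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["metrics"] = m_path
    return paths


def read_lm_events(path) -> list[LMEvent]:
    """Read back an ``lm_events.csv`` file written by :func:`write_results`."""
    events = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            flags = set(filter(None, row["flags"].split("|")))
            run_id = row["run_id"]
            events.append(
                LMEvent(
                    onset_s=float(row["onset_s"]),
                    offset_s=float(row["offset_s"]),
                    state=row["state"],
                    flags=flags,
                    run_id=None if run_id == "" else int(run_id),
                )
            )
    return events
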