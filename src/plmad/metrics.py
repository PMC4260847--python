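"""PLM run classification and subject-level indices.

A PLM run is four or more consecutive retained LMs whose onset-to-onset
inter-movement intervals (IMIs) all lie within [5, 90] s; runs continue
across sleep-wake transitions.  From the runs we derive PLMS/h and PLMW/h,
the periodicity index, first/second-half night ratios, and the PLM-locked
heart-rate delta and slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .model import Hypnogram, LMEvent, SignalTrace, SubjectMetrics, SLEEP_STAGES

__all__ = [
    "PLMRun",
    "HRResponse",
    "find_plm_runs",
    "plm_indices",
    "periodicity_index",
    "night_ratio",
    "detect_r_peaks",
    "hr_response",
    "aggregate_hr",
    "compute_subject_metrics",
]

log = logging.getLogger(__name__)


@dataclass
class PLMRun:
    """A maximal run of periodic leg movements."""

    lm_ids: list[int]  # indices into the retained-LM list
    imis_s: list[float]

    def __post_init__(self) -> None:
        if len(self.lm_ids) < 2:
            raise ValueError("a run needs at least 2 members")
        if len(self.imis_s) != len(self.lm_ids) - 1:
            raise ValueError("need exactly one IMI per consecutive pair")

    def __len__(self) -> int:
        return len(self.lm_ids)


@dataclass
class HRResponse:
    """Normalized heart-rate course around one PLM onset."""

    pre_hr: np.ndarray  # 10 baseline-subtracted bpm values before onset
    post_hr: np.ndarray  # 10 after
    delta: float  # max(post) - min(pre), bpm
    slope: float  # delta / cycles between min and max, bpm per cycle


def find_plm_runs(
    lms: Sequence[LMEvent],
    imi_min_s: float = 5.0,
    imi_max_s: float = 90.0,
    min_run: int = 4,
    short_imi: str = "break",
) -> list[PLMRun]:
    """Group retained LMs into maximal periodic runs.

    ``short_imi='break'`` terminates a chain at any IMI below ``imi_min_s``
    (the LM that arrived too early starts a fresh chain).  With
    ``short_imi='ignore'`` the too-early movement is skipped and the IMI is
    measured to the next movement instead.  Run membership is recorded by
    writing ``run_id`` onto the input events.
    """
    onsets = [ev.onset_s for ev in lms]
    if onsets != sorted(onsets):
        raise ValueError("LM events must be sorted by onset")

    runs: list[PLMRun] = []

    if short_imi == "break":
        chain = [0] if lms else []
        for i in range(1, len(lms)):
            imi = onsets[i] - onsets[chain[-1]] if chain else None
            if chain and imi_min_s <= imi <= imi_max_s:
                chain.append(i)
            else:
                if len(chain) >= min_run:
                    runs.append(_make_run(chain, onsets))
                chain = [i]
        if len(chain) >= min_run:
            runs.append(_make_run(chain, onsets))
    elif short_imi == "ignore":
        chain = [0] if lms else []
        for i in range(1, len(lms)):
            if not chain:
                chain = [i]
                continue
            imi = onsets[i] - onsets[chain[-1]]
            if imi < imi_min_s:
                continue  # intervening movement is ignored
            if imi <= imi_max_s:
                chain.append(i)
            else:
                if len(chain) >= min_run:
                    runs.append(_make_run(chain, onsets))
                chain = [i]
        if len(chain) >= min_run:
            runs.append(_make_run(chain, onsets))
    else:
        raise ValueError(f"short_imi must be 'break' or 'ignore', got {short_imi!r}")

    for run_id, run in enumerate(runs):
        for idx in run.lm_ids:
            lms[idx].run_id = run_id
    return runs


def _make_run(chain: list[int], onsets: list[float]) -> PLMRun:
    imis = [onsets[b] - onsets[a] for a, b in zip(chain, chain[1:])]
    return PLMRun(lm_ids=list(chain), imis_s=imis)


def plm_indices(
    runs: Sequence[PLMRun],
    lms: Sequence[LMEvent],
    hypnogram: Hypnogram,
    span_s: Optional[float] = None,
) -> tuple[Optional[float], Optional[float], int, int]:
    """(PLMS/h, PLMW/h, lm_count, plm_count).

    A run member counts toward PLMS when the epoch containing its onset is
    sleep and toward PLMW when it is wake; indices are per hour of total
    sleep/wake time.  An index is ``None`` when the corresponding
    denominator is zero.
    """
    member_ids = sorted({i for run in runs for i in run.lm_ids})
    plm_count = len(member_ids)
    lm_count = len(lms)

    n_sleep = sum(1 for i in member_ids if hypnogram.stage_at(lms[i].onset_s) in SLEEP_STAGES)
    n_wake = sum(1 for i in member_ids if hypnogram.stage_at(lms[i].onset_s) == "W")

    tst_h = hypnogram.total_sleep_s(span_s) / 3600.0
    wake_h = hypnogram.total_wake_s(span_s) / 3600.0
    plms_per_h = (n_sleep / tst_h) if tst_h > 0 else None
    plmw_per_h = (n_wake / wake_h) if wake_h > 0 else None
    return plms_per_h, plmw_per_h, lm_count, plm_count


def periodicity_index(
    lms: Sequence[LMEvent],
    state_filter: Optional[str] = None,
    hypnogram: Optional[Hypnogram] = None,
    imi_min_s: float = 10.0,
    imi_max_s: float = 90.0,
    min_seq: int = 3,
) -> Optional[float]:
    """Fraction of IMIs in [imi_min, imi_max) occurring in sequences of
    ``min_seq`` or more consecutive such intervals, over all IMIs.

    ``state_filter`` restricts to LMs whose onset epoch is ``"sleep"`` or
    ``"wake"``.  Returns ``None`` (undefined) with fewer than 2 qualifying
    movements.
    """
    events = list(lms)
    if state_filter is not None:
        if hypnogram is None:
            raise ValueError("state_filter requires a hypnogram")
        if state_filter == "sleep":
            events = [e for e in events if hypnogram.stage_at(e.onset_s) in SLEEP_STAGES]
        elif state_filter == "wake":
            events = [e for e in events if hypnogram.stage_at(e.onset_s) == "W"]
        else:
            raise ValueError("state_filter must be 'sleep' or 'wake'")
    if len(events) < 2:
        return None
    onsets = np.array(sorted(e.onset_s for e in events))
    imis = np.diff(onsets)
    ok = (imis >= imi_min_s) & (imis < imi_max_s)
    qualifying = 0
    i = 0
    n = ok.size
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if j - i >= min_seq:
                qualifying += j - i
            i = j
        else:
            i += 1
    return qualifying / n


def night_ratio(
    onsets: Sequence[float], study_span_s: float
) -> Optional[float]:
    """First-half / second-half event-count ratio; ``None`` when either
    half has zero events."""
    if study_span_s <= 0:
        raise ValueError("study span must be positive")
    mid = study_span_s / 2.0
    first = sum(1 for t in onsets if t < mid)
    second = len(list(onsets)) - first
    if first == 0 or second == 0:
        return None
    return first / second


def detect_r_peaks(ecg: SignalTrace) -> np.ndarray:
    """R-peak times (seconds) via a Pan-Tompkins-style energy detector.

    Band-pass (5-25 Hz) -> differentiate -> square -> 150 ms moving
    integration -> peak picking with a 250 ms refractory period, peak
    times refined to the local maximum of the rectified band-passed ECG.
    Returns an empty array (with a warning) for flat signals.
    """
    x = ecg.samples
    fs = ecg.fs
    if not np.any(x != x[0]):
        log.warning("flat ECG signal: no R peaks detected")
        return np.array([])

    nyq = fs / 2.0
    hi = min(25.0, 0.9 * nyq)
    lo = min(5.0, hi / 2.0)
    b, a = butter(2, [lo / nyq, hi / nyq], btype="band")
    bp = filtfilt(b, a, x)
    energy = np.gradient(bp) ** 2
    w = max(1, int(round(0.150 * fs)))
    kernel = np.ones(w) / w
    integ = np.convolve(energy, kernel, mode="same")

    height = 0.2 * np.percentile(integ, 99.5)
    if height <= 0:
        log.warning("ECG energy is zero: no R peaks detected")
        return np.array([])
    locs, _ = find_peaks(integ, height=height, distance=max(1, int(round(0.25 * fs))))

    # refine each detection to the nearby rectified-ECG maximum
    half = max(1, int(round(0.075 * fs)))
    rect = np.abs(bp)
    refined = []
    for loc in locs:
        i0 = max(0, loc - half)
        i1 = min(len(rect), loc + half + 1)
        refined.append(i0 + int(np.argmax(rect[i0:i1])))
    peaks = np.unique(refined)
    return ecg.start_time + peaks / fs


def hr_response(
    r_peaks: np.ndarray, plm_onset: float, n_cycles: int = 10
) -> Optional[HRResponse]:
    """Normalized heart-rate course around one PLM onset.

    Instantaneous HR per cardiac cycle is 60/RR.  The cycle immediately
    preceding onset is the baseline; its HR is subtracted from the
    ``n_cycles`` values before and after onset.  ``delta`` is the largest
    post-onset value minus the smallest pre-onset value, and ``slope`` is
    delta divided by the number of cycles between those two positions.
    Returns ``None`` when fewer than ``n_cycles`` cycles exist on either
    side.
    """
    r = np.asarray(r_peaks, dtype=np.float64)
    if r.size < 2:
        return None
    rr = np.diff(r)
    hr = 60.0 / rr  # hr[i] is the rate of the cycle [r[i], r[i+1])
    n_cyc = hr.size

    # baseline: last cycle ending at or before onset
    ends = r[1:]
    b = int(np.searchsorted(ends, plm_onset, side="right")) - 1
    if b < n_cycles - 1 or b + n_cycles >= n_cyc:
        return None
    norm = hr - hr[b]
    pre = norm[b - n_cycles + 1 : b + 1]
    post = norm[b + 1 : b + 1 + n_cycles]
    i_min = b - n_cycles + 1 + int(np.argmin(pre))
    i_max = b + 1 + int(np.argmax(post))
    delta = float(norm[i_max] - norm[i_min])
    cycles_apart = max(1, i_max - i_min)
    return HRResponse(
        pre_hr=pre.copy(),
        post_hr=post.copy(),
        delta=delta,
        slope=delta / cycles_apart,
    )


def aggregate_hr(
    r_peaks: np.ndarray,
    plm_onsets: Sequence[float],
    n_cycles: int = 10,
) -> tuple[Optional[float], Optional[float], int]:
    """Mean HR delta/slope across PLMs; returns (delta, slope, n_skipped)."""
    deltas, slopes, skipped = [], [], 0
    for onset in plm_onsets:
        resp = hr_response(r_peaks, onset, n_cycles)
        if resp is None:
            skipped += 1
            continue
        deltas.append(resp.delta)
        slopes.append(resp.slope)
    if not deltas:
        return None, None, skipped
    return float(np.mean(deltas)), float(np.mean(slopes)), skipped


def compute_subject_metrics(
    lms: Sequence[LMEvent],
    runs: Sequence[PLMRun],
    hypnogram: Hypnogram,
    study_span_s: float,
    r_peaks: Optional[np.ndarray] = None,
    hr_n_cycles: int = 10,
    periodicity_kw: Optional[dict] = None,
) -> SubjectMetrics:
    """Assemble the full subject-level metric set.

    ``lms`` must be the retained (post-exclusion) events; run membership
    (``run_id``) must already be assigned by :func:`find_plm_runs`.
    """
    pkw = periodicity_kw or {}
    plms_h, plmw_h, lm_count, plm_count = plm_indices(runs, lms, hypnogram, study_span_s)
    member = [lms[i] for run in runs for i in run.lm_ids]
    member_onsets = sorted(e.onset_s for e in member)
    all_onsets = sorted(e.onset_s for e in lms)

    hr_delta = hr_slope = None
    if r_peaks is not None and len(member_onsets):
        hr_delta, hr_slope, skipped = aggregate_hr(r_peaks, member_onsets, hr_n_cycles)
        if skipped:
            log.info("hr_response: %d PLMs skipped (insufficient cardiac cycles)", skipped)

    reliable = study_span_s >= 2 * 3600
    if not reliable:
        log.warning("recording spans %.2f h (< 2 h): metrics marked unreliable",
                    study_span_s / 3600)

    return SubjectMetrics(
        plms_per_h=plms_h if plms_h is not None else None,
        plmw_per_h=plmw_h if plmw_h is not None else None,
        lm_count=lm_count,
        plm_count=plm_count,
        periodicity_sleep=periodicity_index(lms, "sleep", hypnogram, **pkw),
        periodicity_wake=periodicity_index(lms, "wake", hypnogram, **pkw),
        night_ratio_plm=night_ratio(member_onsets, study_span_s),
        night_ratio_lm=night_ratio(all_onsets, study_span_s),
        hr_delta_mean=hr_delta,
        hr_slope_mean=hr_slope,
        hours_sleep=hypnogram.total_sleep_s(study_span_s) / 3600.0,
        hours_wake=hypnogram.total_wake_s(study_span_s) / 3600.0,
        reliable=reliable,
    )
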