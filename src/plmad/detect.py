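"""Candidate leg-movement detection.

The detector compares a short RMS envelope of the cleaned leg-EMG signal
against the three dynamic thresholds (alpha upper, beta lower, psi falloff)
of a :class:`~plmad.thresholds.VATProfile`:

* a candidate opens at the first sample where the envelope exceeds alpha
  (detector enabled);
* it closes once the envelope stays below beta for the fall time
  (0.05 s); the offset is the last sample at or above psi before that;
* candidates are then bridged (gaps <= 0.1 s), short ones rejected
  (< 0.75 s), survivors merged (gaps <= 2.0 s), long ones rejected
  (> 10 s), and finally screened by time-normalized AUC against half the
  upper threshold to drop fragmentary-myoclonus spikes.

Two full detection passes are run: first-pass detections are substituted
out of the rectified signal before the noise floor and thresholds are
recomputed for the second, final pass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .adaptive import RLSConfig, rls_cancel, self_reference_cancel
from .io import merge_leg_channels, resample_trace
from .model import Hypnogram, LMEvent, Recording, SignalTrace
from .thresholds import (
    VATProfile,
    apply_snr_plus,
    moving_mean,
    noise_floor,
    second_pass_signal,
    thresholds,
)

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "DetectorRules",
    "rms_envelope",
    "detect_candidates",
    "bridge_and_filter",
    "auc_screen",
    "detect_lm",
]

log = logging.getLogger(__name__)

#: Interval representation used between detector stages.
Interval = tuple[float, float, frozenset]


@dataclass(frozen=True)
class DetectorRules:
    """Timing and screening constants of the candidate-LM pipeline."""

    rms_window_s: float = 0.15
    fall_time_s: float = 0.05
    bridge_s: float = 0.1
    min_dur_s: float = 0.75
    merge_s: float = 2.0
    max_dur_s: float = 10.0
    auc_factor: float = 0.5
    auc_mode: str = "normalized"  # normalized | raw
    auc_invert: bool = False  # keep myoclonus candidates instead of LMs
    rms_align: str = "centered"  # centered | trailing

    def __post_init__(self) -> None:
        for name in (
            "rms_window_s",
            "fall_time_s",
            "bridge_s",
            "min_dur_s",
            "merge_s",
            "max_dur_s",
            "auc_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_dur_s >= self.max_dur_s:
            raise ValueError("min_dur_s must be < max_dur_s")


def rms_envelope(
    x: SignalTrace, window_s: float = 0.15, align: str = "centered"
) -> np.ndarray:
    """Short-window RMS of the signal, same length as the input."""
    w = int(round(window_s * x.fs))
    if w < 1:
        raise ValueError(
            f"RMS window of {window_s} s at fs={x.fs} covers no samples"
        )
    sq = x.samples**2
    n = sq.size
    s = np.concatenate(([0.0], np.cumsum(sq, dtype=np.float64)))
    idx = np.arange(n)
    if align == "centered":
        lo = idx - w // 2
    elif align == "trailing":
        lo = idx - w + 1
    else:
        raise ValueError(f"unknown rms alignment {align!r}")
    hi = np.clip(lo + w, 0, n)
    lo = np.clip(lo, 0, n)
    return np.sqrt((s[hi] - s[lo]) / (hi - lo))


@njit(cache=True)
def _candidates_core(y, alpha, beta, psi, enabled, k_fall):  # pragma: no cover
    """Three-threshold state machine; returns sample-index intervals.

    Output arrays: onset index, offset index (half-open), and a flag that
    is 1 when the candidate was still open at the end of the record.
    """
    n = y.shape[0]
    onsets = []
    offsets = []
    open_end = []
    i = 0
    while i < n:
        if enabled[i] and y[i] > alpha[i]:
            onset = i
            j = i + 1
            run = 0
            fall_start = -1
            forced = False
            while j < n:
                if not enabled[j]:
                    fall_start = j
                    forced = True
                    break
                if y[j] < beta[j]:
                    run += 1
                    if run == k_fall:
                        fall_start = j - k_fall + 1
                        break
                else:
                    run = 0
                j += 1
            at_end = fall_start == -1
            if at_end:
                fall_start = n
            # offset: last sample in [onset, fall_start) at or above psi
            k = fall_start - 1
            while k > onset and y[k] < psi[k]:
                k -= 1
            onsets.append(onset)
            offsets.append(k + 1)
            open_end.append(1 if at_end else 0)
            if at_end:
                i = n
            elif forced:
                i = fall_start + 1
            else:
                i = fall_start + k_fall
        else:
            i += 1
    out_on = np.empty(len(onsets), dtype=np.int64)
    out_off = np.empty(len(onsets), dtype=np.int64)
    out_open = np.empty(len(onsets), dtype=np.int64)
    for m in range(len(onsets)):
        out_on[m] = onsets[m]
        out_off[m] = offsets[m]
        out_open[m] = open_end[m]
    return out_on, out_off, out_open


def detect_candidates(
    y: np.ndarray,
    profile: VATProfile,
    rules: DetectorRules = DetectorRules(),
    fs: Optional[float] = None,
    start_time: float = 0.0,
) -> list[Interval]:
    """Run the three-threshold state machine over an RMS envelope.

    Onset is the first sample strictly above alpha while the detector is
    enabled; the candidate closes at the first stretch of ``fall_time_s``
    consecutive samples strictly below beta (or when a disabled region or
    the end of the record is reached), and the offset is placed after the
    last sample at or above psi.  Returns ordered, non-overlapping
    ``(onset_s, offset_s, flags)`` intervals.
    """
    fs = fs if fs is not None else profile.fs
    if fs <= 0:
        raise ValueError("sampling rate must be provided via profile.fs or fs")
    y = np.asarray(y, dtype=np.float64)
    if len(y) != len(profile):
        raise ValueError("envelope and threshold profile lengths differ")
    k_fall = max(1, int(round(rules.fall_time_s * fs)))
    on, off, open_end = _candidates_core(
        y,
        np.ascontiguousarray(profile.alpha),
        np.ascontiguousarray(profile.beta),
        np.ascontiguousarray(profile.psi),
        np.ascontiguousarray(profile.enabled),
        k_fall,
    )
    out: list[Interval] = []
    for i in range(on.size):
        flags = frozenset({"open_ended"}) if open_end[i] else frozenset()
        out.append(
            (start_time + on[i] / fs, start_time + off[i] / fs, flags)
        )
    return out


def bridge_and_filter(
    intervals: Sequence[Interval], rules: DetectorRules = DetectorRules()
) -> list[Interval]:
    """Bridge, duration-filter and merge candidate intervals.

    Applied strictly in this order: (1) bridge gaps <= ``bridge_s``;
    (2) reject durations < ``min_dur_s``; (3) merge remaining gaps <=
    ``merge_s``; (4) reject durations > ``max_dur_s``.  Rejected intervals
    are kept in the output with ``too_short``/``too_long`` flags for audit.
    """
    ivs = sorted(intervals, key=lambda t: t[0])

    def join(chunks: list[Interval], max_gap: float, flag: str) -> list[Interval]:
        out: list[Interval] = []
        for on, off, fl in chunks:
            if out and on - out[-1][1] <= max_gap:
                pon, poff, pfl = out[-1]
                out[-1] = (pon, max(poff, off), frozenset(pfl | fl | {flag}))
            else:
                out.append((on, off, fl))
        return out

    bridged = join(ivs, rules.bridge_s, "bridged")

    kept: list[Interval] = []
    rejected: list[Interval] = []
    for on, off, fl in bridged:
        if off - on < rules.min_dur_s:
            rejected.append((on, off, frozenset(fl | {"too_short"})))
        else:
            kept.append((on, off, fl))

    merged = join(kept, rules.merge_s, "merged")

    final: list[Interval] = []
    for on, off, fl in merged:
        if off - on > rules.max_dur_s:
            rejected.append((on, off, frozenset(fl | {"too_long"})))
        else:
            final.append((on, off, fl))

    return sorted(final + rejected, key=lambda t: (t[0], t[1]))


def auc_screen(
    x_clean: SignalTrace,
    intervals: Sequence[Interval],
    profile: VATProfile,
    rules: DetectorRules = DetectorRules(),
) -> list[tuple[float, float, frozenset, float]]:
    """Screen candidates by trapezoidal AUC of the rectified signal.

    The AUC over each interval is time-normalized (divided by the interval
    duration, giving a mean amplitude in uV) and compared to
    ``auc_factor`` times the mean upper threshold over the interval;
    candidates below it are flagged ``auc_rejected`` (fragmentary
    myoclonus and other transients).  With ``rules.auc_invert`` the
    comparison is flipped, flagging stable movements instead, which turns
    the detector into a fragmentary-myoclonus finder.  Returns
    ``(onset, offset, flags, auc_norm_uv)`` tuples.
    """
    rect = np.abs(x_clean.samples)
    fs = x_clean.fs
    n = rect.size
    out = []
    for on, off, fl in intervals:
        i0 = max(0, int(round((on - x_clean.start_time) * fs)))
        # include the sample at the interval's right edge so the trapezoid
        # spans the full duration
        i1 = min(n, int(round((off - x_clean.start_time) * fs)) + 1)
        if i1 - i0 < 2:
            raise ValueError(f"interval [{on}, {off}) covers < 2 samples")
        area = float(np.trapezoid(rect[i0:i1], dx=1.0 / fs))
        if rules.auc_mode == "normalized":
            value = area / (off - on)
        elif rules.auc_mode == "raw":
            value = area
        else:
            raise ValueError(f"unknown auc_mode {rules.auc_mode!r}")
        limit = rules.auc_factor * float(np.mean(profile.alpha[i0:i1]))
        keep = value >= limit
        if rules.auc_invert:
            keep = not keep
        if not keep:
            fl = frozenset(fl | {"auc_rejected"})
        out.append((on, off, fl, value))
    return out


def _pick_leg_traces(recording: Recording) -> list[SignalTrace]:
    if "leg_left" in recording and "leg_right" in recording:
        return [recording["leg_left"], recording["leg_right"]]
    for role in ("leg", "leg_left", "leg_right"):
        if role in recording:
            return [recording[role]]
    raise KeyError(
        "recording has no leg channel; expected roles 'leg_left'/'leg_right' "
        f"or 'leg' among {recording.labels}"
    )


def detect_lm(
    recording: Recording,
    hypnogram: Hypnogram,
    config=None,
) -> list[LMEvent]:
    """Full two-pass candidate-LM detection on a recording.

    Expects channel roles ``leg_left``/``leg_right`` (or a single ``leg``)
    and optionally ``ecg``.  Returns every second-pass candidate as an
    :class:`LMEvent` — retained ones plus duration/AUC-rejected ones with
    audit flags.  Respiratory exclusion and run classification are applied
    downstream.
    """
    if config is None:
        from .config import PipelineConfig

        config = PipelineConfig()

    legs = _pick_leg_traces(recording)
    if len(legs) == 2:
        leg = merge_leg_channels(legs[0], legs[1], rule=config.merge_rule)
    else:
        leg = legs[0]

    if leg.duration_s < 2 * 3600:
        warnings.warn(
            f"recording spans {leg.duration_s / 3600:.2f} h (< 2 h); "
            "subject metrics will be marked unreliable",
            stacklevel=2,
        )

    # -- adaptive cancellation ------------------------------------------
    acfg = config.adaptive
    rls = RLSConfig(
        n_weights=acfg.n_weights,
        forgetting=acfg.forgetting,
        init_delta=acfg.init_delta,
        self_ref_advance=acfg.self_ref_advance,
    )
    mode = acfg.mode
    if mode == "auto":
        mode = "ecg" if "ecg" in recording else "self"
    if mode == "ecg":
        if "ecg" not in recording:
            raise KeyError("adaptive.mode=ecg but recording has no 'ecg' channel")
        ecg = recording["ecg"]
        if ecg.fs != leg.fs:
            ecg = resample_trace(ecg, leg.fs)
            if len(ecg) != len(leg):
                m = min(len(ecg), len(leg))
                ecg = ecg.copy_with(ecg.samples[:m])
                leg = leg.copy_with(leg.samples[:m])
        cleaned = rls_cancel(leg, ecg, rls)
    elif mode == "self":
        cleaned = self_reference_cancel(leg, rls)
    elif mode == "off":
        cleaned = leg
    else:
        raise ValueError(f"unknown adaptive.mode {acfg.mode!r}")

    tcfg = config.thresholds
    rules = config.detector

    # -- SNR+ boost gated on the pre-boost noise floor ------------------
    eta_gate = noise_floor(cleaned, tcfg.noise_window_s)
    if config.snr_plus.enabled:
        working = apply_snr_plus(cleaned, eta_gate, config.snr_plus.gate_uv)
    else:
        working = cleaned

    w_samples = int(round(tcfg.noise_window_s * working.fs))
    rect = np.abs(working.samples)

    def make_profile(rect_sig: np.ndarray) -> VATProfile:
        eta = moving_mean(rect_sig, w_samples)
        return thresholds(
            eta, U=tcfg.U_uv, L=tcfg.L_uv, fs=working.fs, shutoff_uv=tcfg.shutoff_uv
        )

    profile1 = make_profile(rect)
    y = rms_envelope(working, rules.rms_window_s, rules.rms_align)

    # -- pass 1: detect, bridge/filter, substitute ----------------------
    cands1 = detect_candidates(y, profile1, rules, start_time=working.start_time)
    pass1 = [iv for iv in bridge_and_filter(cands1, rules) if _is_kept(iv)]
    rect_trace = working.copy_with(rect)
    pass1_events = [LMEvent(on, off, flags=set(fl)) for on, off, fl in pass1]
    rect2 = second_pass_signal(rect_trace, pass1_events, profile1)

    # -- pass 2: final detection on refreshed thresholds ----------------
    profile2 = make_profile(rect2.samples)
    cands2 = detect_candidates(y, profile2, rules, start_time=working.start_time)
    filtered = bridge_and_filter(cands2, rules)
    kept = [iv for iv in filtered if _is_kept(iv)]
    dropped = [iv for iv in filtered if not _is_kept(iv)]

    screened = auc_screen(working, kept, profile2, rules)

    events: list[LMEvent] = []
    fs = working.fs
    for on, off, fl, auc in screened:
        events.append(_make_event(on, off, fl, auc, y, fs, working.start_time, hypnogram))
    for on, off, fl in dropped:
        events.append(_make_event(on, off, fl, 0.0, y, fs, working.start_time, hypnogram))
    events.sort(key=lambda e: (e.onset_s, e.offset_s))

    n_kept = sum(1 for e in events if e.retained)
    log.info(
        "detect_lm: %d second-pass candidates -> %d retained (%d rejected)",
        len(filtered),
        n_kept,
        len(events) - n_kept,
    )
    return events


def _is_kept(iv: Interval) -> bool:
    return not (iv[2] & {"too_short", "too_long"})


def _make_event(on, off, fl, auc, y, fs, t0, hypnogram: Hypnogram) -> LMEvent:
    i0 = max(0, int(round((on - t0) * fs)))
    i1 = max(i0 + 1, min(y.size, int(round((off - t0) * fs))))
    return LMEvent(
        onset_s=on,
        offset_s=off,
        peak_rms_uv=float(np.max(y[i0:i1])),
        auc_norm_uv=float(auc),
        state=hypnogram.stage_at(on),
        flags=set(fl),
    )
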