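"""Seeded synthetic polysomnography generator with exact ground truth.

Generates leg-EMG channels (Gaussian baseline with a piecewise noise-sigma
schedule, band-limited 20-45 Hz movement bursts, sub-200-ms myoclonic
spikes, ECG leakage), an ECG channel (QRS-like template train), a
hypnogram, respiratory events with optional time-locked leg bursts after
their offsets, and a JSON-serializable ground-truth record of everything
planted.  All randomness derives from the spec's seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .edf import write_edf
from .model import Hypnogram, Recording, RespEvent, SignalTrace

__all__ = ["SynthSpec", "Burst", "Train", "GroundTruth", "SynthResult", "generate", "generate_files"]


@dataclass(frozen=True)
class Burst:
    """One planted leg movement."""

    onset_s: float
    duration_s: float
    amplitude_uv: float  # target RMS of the burst core
    leg: str = "both"  # left | right | both

    def __post_init__(self):
        if not (0.5 <= self.duration_s <= 10.0):
            raise ValueError(
                f"burst duration must lie in [0.5, 10] s, got {self.duration_s}"
            )


@dataclass(frozen=True)
class Train:
    """A periodic schedule of identical bursts."""

    start_s: float
    count: int
    imi_s: float
    duration_s: float = 1.5
    amplitude_uv: float = 25.0
    jitter_s: float = 0.0
    leg: str = "both"


@dataclass
class SynthSpec:
    duration_h: float = 1.0
    fs_hz: float = 200.0
    ecg_fs_hz: Optional[float] = None  # defaults to fs_hz
    baseline_uv: Sequence[tuple[float, float]] = ((0.0, 1.0),)  # (start_s, sigma)
    bursts: Sequence[Burst] = ()
    trains: Sequence[Train] = ()
    myoclonus_rate_per_h: float = 0.0
    myoclonus_amp_uv: float = 30.0
    ecg_hr_bpm: Sequence[tuple[float, float]] = ((0.0, 60.0),)  # (start_s, bpm)
    ecg_amp_uv: float = 500.0
    ecg_leak: float = 0.0  # fraction of the ECG leaking into the EMG
    include_ecg_channel: bool = True
    resp_events: Sequence[tuple[float, float, str]] = ()
    resp_burst_lag_s: Optional[float] = None  # plant a burst at offset + lag
    resp_burst_dur_s: float = 1.5
    resp_burst_amp_uv: float = 25.0
    hypnogram_stages: Optional[Sequence[str]] = None  # explicit 30-s epochs
    epoch_len_s: float = 30.0
    seed: int = 0


@dataclass
class GroundTruth:
    lm_intervals: list[tuple[float, float]] = field(default_factory=list)
    plm_run_memberships: list[list[int]] = field(default_factory=list)
    myoclonus_times: list[float] = field(default_factory=list)
    resp_events: list[tuple[float, float, str]] = field(default_factory=list)
    r_peak_times: list[float] = field(default_factory=list)
    noise_sigma_schedule: list[tuple[float, float]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class SynthResult:
    recording: Recording
    hypnogram: Hypnogram
    resp_events: list[RespEvent]
    ground_truth: GroundTruth


def _qrs_template(fs: float) -> np.ndarray:
    """A QRS-like wavelet (Mexican-hat); periodicity matters, morphology not."""
    width = 0.10
    t = np.arange(-width, width, 1.0 / fs)
    s = 0.02
    return (1 - (t / s) ** 2) * np.exp(-0.5 * (t / s) ** 2)


def _band_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS band-limited (20-45 Hz) noise, the LM burst carrier."""
    pad = max(64, int(fs))
    white = rng.standard_normal(n + 2 * pad)
    nyq = fs / 2.0
    hi = min(45.0, 0.95 * nyq)
    lo = min(20.0, hi / 2)
    b, a = butter(4, [lo / nyq, hi / nyq], btype="band")
    x = filtfilt(b, a, white)[pad : pad + n]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _burst_envelope(n: int, fs: float, ramp_s: float = 0.1) -> np.ndarray:
    """Flat-topped envelope with raised-cosine ramps."""
    r = min(int(round(ramp_s * fs)), n // 2)
    env = np.ones(n)
    if r > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env


def _sigma_per_sample(schedule, n: int, fs: float) -> np.ndarray:
    sched = sorted(schedule)
    sig = np.empty(n)
    for i, (start, sigma) in enumerate(sched):
        i0 = max(0, int(round(start * fs)))
        i1 = n if i + 1 >= len(sched) else min(n, int(round(sched[i + 1][0] * fs)))
        sig[i0:i1] = sigma
    i0_first = int(round(sched[0][0] * fs))
    if i0_first > 0:
        sig[:i0_first] = sched[0][1]
    return sig


def _default_hypnogram(n_epochs: int) -> list[str]:
    """A plausible night: wake onset, then cycling S2/S3/R blocks."""
    stages: list[str] = []
    cycle = ["S1"] * 2 + ["S2"] * 20 + ["S3"] * 14 + ["S2"] * 6 + ["R"] * 12
    stages += ["W"] * 4
    while len(stages) < n_epochs:
        stages += cycle
    return stages[:n_epochs]


def generate(spec: SynthSpec) -> SynthResult:
    """Build the synthetic recording in memory (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    fs = float(spec.fs_hz)
    n = int(round(spec.duration_h * 3600 * fs))
    total_s = n / fs

    gt = GroundTruth(noise_sigma_schedule=[(float(a), float(b)) for a, b in spec.baseline_uv])

    sigma = _sigma_per_sample(spec.baseline_uv, n, fs)
    left = rng.standard_normal(n) * sigma
    right = rng.standard_normal(n) * sigma

    # --- planted bursts (explicit, trains, respiratory-coupled) --------
    bursts: list[Burst] = list(spec.bursts)
    run_groups: list[list[tuple[float, float]]] = []
    for tr in spec.trains:
        group = []
        t = tr.start_s
        for _ in range(tr.count):
            jit = rng.uniform(-tr.jitter_s, tr.jitter_s) if tr.jitter_s > 0 else 0.0
            onset = t + jit
            b = Burst(onset, tr.duration_s, tr.amplitude_uv, tr.leg)
            bursts.append(b)
            group.append((b.onset_s, b.onset_s + b.duration_s))
            t += tr.imi_s
        run_groups.append(group)

    resp_list = [RespEvent(a, b, c) for a, b, c in spec.resp_events]
    gt.resp_events = [(e.onset_s, e.offset_s, e.type) for e in resp_list]
    if spec.resp_burst_lag_s is not None:
        for ev in resp_list:
            onset = ev.offset_s + spec.resp_burst_lag_s
            if onset + spec.resp_burst_dur_s < total_s:
                bursts.append(
                    Burst(onset, spec.resp_burst_dur_s, spec.resp_burst_amp_uv, "both")
                )

    bursts.sort(key=lambda b: b.onset_s)
    merged_intervals: list[tuple[float, float]] = []
    for b in bursts:
        i0 = int(round(b.onset_s * fs))
        i1 = min(n, i0 + int(round(b.duration_s * fs)))
        if i1 <= i0:
            continue
        carrier = _band_noise(rng, i1 - i0, fs)
        wave = carrier * _burst_envelope(i1 - i0, fs) * b.amplitude_uv
        if b.leg in ("left", "both"):
            left[i0:i1] += wave
        if b.leg in ("right", "both"):
            right[i0:i1] += wave
        iv = (i0 / fs, i1 / fs)
        if merged_intervals and iv[0] <= merged_intervals[-1][1]:
            prev = merged_intervals[-1]
            merged_intervals[-1] = (prev[0], max(prev[1], iv[1]))
        else:
            merged_intervals.append(iv)
    gt.lm_intervals = merged_intervals

    # run memberships as indices into gt.lm_intervals
    for group in run_groups:
        ids = []
        for on, off in group:
            for k, (a, b_) in enumerate(merged_intervals):
                if a <= on < b_:
                    ids.append(k)
                    break
        gt.plm_run_memberships.append(sorted(set(ids)))

    # --- fragmentary myoclonus spikes ----------------------------------
    n_spikes = rng.poisson(spec.myoclonus_rate_per_h * spec.duration_h)
    for _ in range(n_spikes):
        t0 = rng.uniform(0, total_s - 0.2)
        width = rng.uniform(0.03, 0.15)  # always < 200 ms
        i0 = int(round(t0 * fs))
        i1 = min(n, i0 + max(2, int(round(width * fs))))
        shape = np.hanning(i1 - i0) * spec.myoclonus_amp_uv
        burst_sign = rng.choice([-1.0, 1.0])
        left[i0:i1] += shape * burst_sign
        right[i0:i1] += shape * burst_sign
        gt.myoclonus_times.append(t0)
    gt.myoclonus_times.sort()

    # --- ECG channel and leakage ---------------------------------------
    ecg_fs = float(spec.ecg_fs_hz or fs)
    n_ecg = int(round(total_s * ecg_fs))
    ecg = np.zeros(n_ecg)
    hr_sched = sorted(spec.ecg_hr_bpm)
    t = 0.1
    r_times = []
    while t < total_s - 0.2:
        r_times.append(t)
        bpm = hr_sched[0][1]
        for start, rate in hr_sched:
            if t >= start:
                bpm = rate
        t += 60.0 / bpm
    tpl = _qrs_template(ecg_fs)
    half = len(tpl) // 2
    for rt in r_times:
        c = int(round(rt * ecg_fs))
        i0, i1 = c - half, c - half + len(tpl)
        if i0 < 0 or i1 > n_ecg:
            continue
        ecg[i0:i1] += tpl * spec.ecg_amp_uv
    gt.r_peak_times = [float(v) for v in r_times]

    if spec.ecg_leak:
        tpl_leg = _qrs_template(fs)
        half_leg = len(tpl_leg) // 2
        for rt in r_times:
            c = int(round(rt * fs))
            i0, i1 = c - half_leg, c - half_leg + len(tpl_leg)
            if i0 < 0 or i1 > n:
                continue
            leak = tpl_leg * spec.ecg_amp_uv * spec.ecg_leak
            left[i0:i1] += leak
            right[i0:i1] += leak

    traces = {
        "LAT": SignalTrace(left, fs, "LAT"),
        "RAT": SignalTrace(right, fs, "RAT"),
    }
    if spec.include_ecg_channel:
        traces["ECG"] = SignalTrace(ecg, ecg_fs, "ECG")
    recording = Recording(traces=traces, duration_s=total_s, meta={"seed": spec.seed})

    n_epochs = math.ceil(total_s / spec.epoch_len_s)
    if spec.hypnogram_stages is not None:
        stages = list(spec.hypnogram_stages)
        if len(stages) < n_epochs:
            stages += [stages[-1]] * (n_epochs - len(stages))
    else:
        stages = _default_hypnogram(n_epochs)
    hyp = Hypnogram(stages=stages, epoch_len_s=spec.epoch_len_s)

    return SynthResult(recording, hyp, resp_list, gt)


def generate_files(spec: SynthSpec, out_dir) -> dict[str, Path]:
    """Generate and write EDF + hypnogram CSV + respiratory CSV + truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = generate(spec)

    edf_path = out_dir / "recording.edf"
    write_edf(edf_path, res.recording.traces)

    hyp_path = out_dir / "hypnogram.csv"
    with open(hyp_path, "w") as fh:
        fh.write("epoch_index,stage\n")
        for i, st in enumerate(res.hypnogram.stages):
            fh.write(f"{i},{st}\n")

    resp_path = out_dir / "resp_events.csv"
    with open(resp_path, "w") as fh:
        fh.write("onset_s,offset_s,type\n")
        for ev in res.resp_events:
            fh.write(f"{ev.onset_s},{ev.offset_s},{ev.type}\n")

    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(res.ground_truth.to_json() + "\n")

    return {
        "edf": edf_path,
        "hypnogram": hyp_path,
        "resp_events": resp_path,
        "ground_truth": gt_path,
    }
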