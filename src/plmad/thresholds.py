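"""Noise-floor tracking and variable amplitude thresholds.

The detection thresholds ride on a 20-s moving average of the rectified
leg-EMG signal (the noise floor, eta).  For each sample:

    alpha(n) = U * (1 + ln(1 + eta(n) / L))   upper (onset) threshold
    beta(n)  = 0.25 * alpha(n)                lower (release) threshold
    psi(n)   = (alpha(n) + beta(n)) / 2       falloff (offset) threshold

so alpha equals the 8-uV constant when the floor is zero, grows
logarithmically with noise, and the lower/upper ratio stays at the
2 uV / 8 uV = 0.25 constant ratio.  Detection is disabled wherever the
noise floor exceeds 50 uV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import LMEvent, SignalTrace

__all__ = [
    "VATProfile",
    "noise_floor",
    "thresholds",
    "apply_snr_plus",
    "second_pass_signal",
    "moving_mean",
]

#: Noise-floor level (uV) above which the detector shuts off.
SHUTOFF_UV = 50.0


@dataclass
class VATProfile:
    """Per-sample dynamic thresholds and detector-enabled mask."""

    eta: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    psi: np.ndarray
    enabled: np.ndarray
    fs: float
    U: float = 8.0
    L: float = 2.0

    def __len__(self) -> int:
        return int(self.eta.size)


def moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    The window covers ``[n - window//2, n + window//2]`` inclusive, clipped
    to the signal, and the mean is taken over the samples actually covered.
    """
    n = x.size
    half = window // 2
    s = np.concatenate(([0.0], np.cumsum(x, dtype=np.float64)))
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    return (s[hi] - s[lo]) / (hi - lo)


def noise_floor(x: SignalTrace, window_s: float = 20.0) -> np.ndarray:
    """Per-sample noise floor: moving average of the rectified signal.

    The window spans ``window_s`` seconds centered on each sample (twice
    the maximum LM duration), shrinking at the record edges.
    """
    w = int(round(window_s * x.fs))
    if w < 2:
        raise ValueError(
            f"noise window of {window_s} s at fs={x.fs} covers fewer than 2 samples"
        )
    return moving_mean(np.abs(x.samples), w)


def thresholds(
    eta: np.ndarray,
    U: float = 8.0,
    L: float = 2.0,
    fs: float = 0.0,
    shutoff_uv: float = SHUTOFF_UV,
) -> VATProfile:
    """Build the per-sample threshold profile from a noise floor."""
    if not (U > L > 0):
        raise ValueError(f"need U > L > 0, got U={U}, L={L}")
    eta = np.asarray(eta, dtype=np.float64)
    if np.any(eta < 0):
        raise ValueError("noise floor contains negative values")
    alpha = U * (1.0 + np.log1p(eta / L))
    beta = 0.25 * alpha
    psi = 0.5 * (alpha + beta)
    enabled = eta <= shutoff_uv
    return VATProfile(
        eta=eta, alpha=alpha, beta=beta, psi=psi, enabled=enabled, fs=fs, U=U, L=L
    )


def apply_snr_plus(
    x: SignalTrace, eta: np.ndarray, gate_uv: float = 2.0
) -> SignalTrace:
    """Boost weak signal where the noise floor is low (the SNR+ option).

    A two-tap FIR summing filter, ``x(n) + x(n-1)``, doubles amplitude at
    DC and attenuates above one third of the sampling rate (33 Hz at
    100 Hz).  It is applied only at samples where ``eta < gate_uv``; other
    samples are passed through unchanged.  Sample 0 is never modified.
    """
    if len(eta) != len(x):
        raise ValueError("eta length must match signal length")
    out = x.samples.copy()
    boosted = x.samples.copy()
    boosted[1:] = x.samples[1:] + x.samples[:-1]
    mask = np.asarray(eta) < gate_uv
    mask = mask.copy()
    mask[0] = False
    out[mask] = boosted[mask]
    return x.copy_with(out)


def snr_plus_gain(freq_hz: np.ndarray, fs: float) -> np.ndarray:
    """Magnitude response of the two-tap summing filter |1 + exp(-2j*pi*f/fs)|."""
    freq_hz = np.asarray(freq_hz, dtype=np.float64)
    return np.abs(2.0 * np.cos(np.pi * freq_hz / fs))


def second_pass_signal(
    x: SignalTrace,
    first_pass_lms: list[LMEvent],
    profile: VATProfile,
) -> SignalTrace:
    """Substitute first-pass LM regions before recomputing the noise floor.

    Samples of the rectified signal inside any first-pass LM interval are
    replaced with ``beta(n)/2``; overlapping intervals are substituted once
    (the substitution is idempotent over the union).
    """
    out = x.samples.copy()
    n = len(out)
    half_beta = 0.5 * profile.beta
    for ev in first_pass_lms:
        i0 = max(0, int(round((ev.onset_s - x.start_time) * x.fs)))
        i1 = min(n, int(round((ev.offset_s - x.start_time) * x.fs)))
        if i1 <= i0:
            continue
        out[i0:i1] = half_beta[i0:i1]
    return x.copy_with(out)
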