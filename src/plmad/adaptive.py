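"""Recursive-least-squares adaptive cancellation of cardiac interference.

Two modes are provided: cancellation against a recorded ECG reference
channel, and a single-channel mode that uses a time-advanced copy of the
leg-EMG channel itself as the reference.  The short filter adapts to the
highly periodic cardiac component while broadband muscle bursts pass
through.  Both return the canceller's error sequence (the input minus the
filter's prediction from the reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import SignalTrace

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = ["RLSConfig", "rls_cancel", "self_reference_cancel"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RLSConfig:
    """Hyperparameters for the exponentially-weighted RLS canceller."""

    n_weights: int = 5
    forgetting: float = 0.999
    init_delta: float = 100.0
    self_ref_advance: int = 5

    def __post_init__(self) -> None:
        if self.n_weights < 1:
            raise ValueError("n_weights must be >= 1")
        if not (0.0 < self.forgetting <= 1.0):
            raise ValueError("forgetting factor must lie in (0, 1]")
        if self.init_delta <= 0:
            raise ValueError("init_delta must be positive")


@njit(cache=True)
def _rls_core(d, r, m, lam, delta, start):  # pragma: no cover - compiled
    """EW-RLS error sequence: e(n) = d(n) - w . [r(n) ... r(n-m+1)].

    ``start`` samples at the head are copied through unchanged (warm-up).
    P is initialised to delta * I.
    """
    n = d.shape[0]
    e = np.empty(n)
    w = np.zeros(m)
    p = np.eye(m) * delta
    u = np.zeros(m)
    for i in range(n):
        if i < start:
            e[i] = d[i]
            continue
        for j in range(m):
            u[j] = r[i - j]
        pu = p @ u
        denom = lam + u @ pu
        k = pu / denom
        y = w @ u
        err = d[i] - y
        e[i] = err
        w = w + k * err
        p = (p - np.outer(k, pu)) / lam
        # enforce symmetry; P drifts asymmetric over long records and the
        # recursion then diverges
        p = 0.5 * (p + p.T)
    return e


def rls_cancel(
    signal: SignalTrace, reference: SignalTrace, cfg: RLSConfig = RLSConfig()
) -> SignalTrace:
    """Cancel interference correlated with ``reference`` out of ``signal``.

    Returns the RLS error sequence — the signal minus the filter's
    prediction from the reference — with the first ``n_weights`` samples
    (filter warm-up) passed through unmodified.  A constant-zero reference
    makes this a no-op (warning logged).
    """
    if signal.fs != reference.fs:
        raise ValueError(
            f"signal fs {signal.fs} != reference fs {reference.fs}; resample first"
        )
    if len(signal) != len(reference):
        raise ValueError(
            f"signal length {len(signal)} != reference length {len(reference)}"
        )
    if not np.any(reference.samples):
        log.warning("constant-zero reference: adaptive cancellation skipped")
        return signal.copy_with(signal.samples.copy())

    out = _rls_core(
        np.ascontiguousarray(signal.samples),
        np.ascontiguousarray(reference.samples),
        cfg.n_weights,
        cfg.forgetting,
        cfg.init_delta,
        cfg.n_weights,
    )
    return signal.copy_with(out)


def self_reference_cancel(
    signal: SignalTrace, cfg: RLSConfig = RLSConfig()
) -> SignalTrace:
    """Cancel periodic interference using the signal's own delayed copy.

    The filter predicts x(n) from [x(n-a), ..., x(n-a-m+1)] where ``a`` is
    ``cfg.self_ref_advance``; the prediction error is returned.  Periodic
    components (QRS spikes) are predictable across the advance and are
    removed; broadband EMG bursts are not and pass through.
    """
    if cfg.self_ref_advance < 1:
        raise ValueError("self_ref_advance must be >= 1")
    if cfg.self_ref_advance >= len(signal):
        raise ValueError(
            f"self_ref_advance {cfg.self_ref_advance} >= signal length {len(signal)}"
        )
    x = np.ascontiguousarray(signal.samples)
    delayed = np.empty_like(x)
    a = cfg.self_ref_advance
    delayed[:a] = 0.0
    delayed[a:] = x[:-a]
    start = cfg.n_weights + a
    out = _rls_core(x, delayed, cfg.n_weights, cfg.forgetting, cfg.init_delta, start)
    return signal.copy_with(out)
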