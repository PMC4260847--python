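"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive per-sample/per-element reimplementations of
the documented contracts, kept free of any code shared with the package.
"""

from __future__ import annotations

import numpy as np


def brute_moving_mean(x, window: int) -> np.ndarray:
    """O(N*W) centered moving mean with shrinking edge windows."""
    x = np.asarray(x, dtype=float)
    n = x.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def brute_rms(x, window: int) -> np.ndarray:
    """O(N*W) centered RMS with shrinking edge windows."""
    x = np.asarray(x, dtype=float)
    n = x.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - window // 2)
        hi = min(n, i - window // 2 + window)
        lo2 = max(0, lo)
        out[i] = np.sqrt(np.mean(x[lo2:hi] ** 2))
    return out


def simulate_state_machine(y, alpha, beta, psi, enabled, k_fall):
    """Per-sample simulation of the three-threshold detector contract.

    Returns a list of (onset_idx, offset_idx, open_ended) tuples with the
    offset exclusive.  Onset triggers strictly above alpha while enabled;
    the candidate closes at the first run of ``k_fall`` consecutive samples
    strictly below beta (or at a disabled sample / end of record), with the
    offset placed after the last sample at or above psi; scanning resumes
    after the fall window (after the disabled sample in the forced case).
    """
    n = len(y)
    events = []
    i = 0
    while i < n:
        if enabled[i] and y[i] > alpha[i]:
            onset = i
            j = i + 1
            consecutive = 0
            fall_start = None
            forced = False
            while j < n:
                if not enabled[j]:
                    fall_start = j
                    forced = True
                    break
                if y[j] < beta[j]:
                    consecutive += 1
                    if consecutive == k_fall:
                        fall_start = j - k_fall + 1
                        break
                else:
                    consecutive = 0
                j += 1
            open_ended = fall_start is None
            if open_ended:
                fall_start = n
            k = fall_start - 1
            while k > onset and y[k] < psi[k]:
                k -= 1
            events.append((onset, k + 1, open_ended))
            if open_ended:
                break
            i = fall_start + 1 if forced else fall_start + k_fall
        else:
            i += 1
    return events


def brute_plm_runs(onsets, imi_min=5.0, imi_max=90.0, min_run=4):
    """Exhaustive maximal-window search for qualifying PLM runs.

    Returns member-index lists.  A window [i, j] qualifies when every
    successive IMI inside it lies in [imi_min, imi_max]; runs are the
    maximal such windows with at least ``min_run`` members.
    """
    onsets = list(onsets)
    n = len(onsets)
    ok = [imi_min <= onsets[k + 1] - onsets[k] <= imi_max for k in range(n - 1)]
    runs = []
    i = 0
    while i < n - 1:
        if ok[i]:
            j = i
            while j < n - 1 and ok[j]:
                j += 1
            members = list(range(i, j + 1))
            if len(members) >= min_run:
                runs.append(members)
            i = j
        else:
            i += 1
    return runs


def brute_hr_delta_slope(r_peaks, onset, n_cycles=10):
    """Direct arithmetic for the PLM heart-rate delta and slope."""
    r = list(r_peaks)
    hr = [60.0 / (r[i + 1] - r[i]) for i in range(len(r) - 1)]
    b = None
    for i in range(len(hr)):
        if r[i + 1] <= onset:
            b = i
    if b is None or b < n_cycles - 1 or b + n_cycles >= len(hr):
        return None
    norm = [v - hr[b] for v in hr]
    pre_idx = list(range(b - n_cycles + 1, b + 1))
    post_idx = list(range(b + 1, b + 1 + n_cycles))
    i_min = min(pre_idx, key=lambda i: norm[i])
    i_max = max(post_idx, key=lambda i: norm[i])
    delta = norm[i_max] - norm[i_min]
    return delta, delta / max(1, i_max - i_min)
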