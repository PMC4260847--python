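"""Minimal EDF (European Data Format) reader and writer.

Implements the plain 16-bit EDF layout: a 256-byte fixed header, 256 bytes
per signal, then data records of little-endian int16 samples.  Supports
per-signal sampling rates.  Only the features needed for polysomnography
round-trips are implemented (no EDF+ annotations, no discontinuous files).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .model import Recording, SignalTrace

__all__ = ["read_edf", "write_edf", "EDFFormatError"]

_DIG_MIN = -32768
_DIG_MAX = 32767


class EDFFormatError(ValueError):
    """Raised when a file does not parse as EDF."""


def _fixed(text: str, width: int) -> bytes:
    raw = text.encode("ascii")
    if len(raw) > width:
        raise ValueError(f"field {text!r} exceeds {width} bytes")
    return raw.ljust(width)


def _num(value: float, width: int) -> bytes:
    """Format a number into EDF's fixed-width ascii numeric field."""
    s = f"{value:.10g}"
    if len(s) > width:
        s = f"{value:.{max(width - 7, 1)}g}"
    if len(s) > width:
        raise ValueError(f"cannot format {value} in {width} chars")
    return _fixed(s, width)


def write_edf(
    path,
    traces: dict[str, SignalTrace],
    *,
    record_duration_s: float = 1.0,
    startdate: str = "01.01.01",
    starttime: str = "00.00.00",
    patient: str = "X X X X",
    recording_id: str = "Startdate 01-JAN-2001 X X X",
) -> None:
    """Write traces to ``path`` as a 16-bit EDF file.

    Each signal's sampling rate times ``record_duration_s`` must be an
    integer.  The last record is zero-padded when signal lengths are not a
    whole number of records.  Header date/time default to fixed values so
    output is byte-stable for identical inputs.
    """
    if not traces:
        raise ValueError("no traces to write")
    labels = list(traces)
    spr = {}
    for lab in labels:
        n = traces[lab].fs * record_duration_s
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(
                f"channel {lab!r}: fs={traces[lab].fs} Hz does not give an "
                f"integer number of samples per {record_duration_s} s record"
            )
        spr[lab] = int(round(n))

    n_records = max(
        math.ceil(len(traces[lab]) / spr[lab]) for lab in labels
    )

    phys = {}
    scaled = {}
    for lab in labels:
        x = traces[lab].samples
        pmax = float(np.max(np.abs(x)))
        pmax = max(math.ceil(pmax), 1.0)
        phys[lab] = (-pmax, pmax)
        gain = (_DIG_MAX - _DIG_MIN) / (2.0 * pmax)
        offset = _DIG_MIN - (-pmax) * gain
        dig = np.round(x * gain + offset)
        scaled[lab] = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    ns = len(labels)
    header_bytes = 256 * (1 + ns)

    parts = [
        _fixed("0", 8),
        _fixed(patient, 80),
        _fixed(recording_id, 80),
        _fixed(startdate, 8),
        _fixed(starttime, 8),
        _num(header_bytes, 8),
        _fixed("", 44),
        _num(n_records, 8),
        _num(record_duration_s, 8),
        _num(ns, 4),
    ]
    # per-signal header fields, each field grouped across all signals
    parts += [_fixed(lab[:16], 16) for lab in labels]
    parts += [_fixed("", 80) for _ in labels]
    parts += [_fixed("uV", 8) for _ in labels]
    parts += [_num(phys[lab][0], 8) for lab in labels]
    parts += [_num(phys[lab][1], 8) for lab in labels]
    parts += [_num(_DIG_MIN, 8) for _ in labels]
    parts += [_num(_DIG_MAX, 8) for _ in labels]
    parts += [_fixed("", 80) for _ in labels]
    parts += [_num(spr[lab], 8) for lab in labels]
    parts += [_fixed("", 32) for _ in labels]

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        zero_dig = {
            lab: np.int16(round(_DIG_MIN + (_DIG_MAX - _DIG_MIN) / 2.0))
            for lab in labels
        }
        for rec in range(n_records):
            for lab in labels:
                n = spr[lab]
                chunk = scaled[lab][rec * n : (rec + 1) * n]
                if len(chunk) < n:
                    pad = np.full(n - len(chunk), zero_dig[lab], dtype="<i2")
                    chunk = np.concatenate([chunk, pad])
                fh.write(chunk.tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file into a :class:`Recording` (amplitudes in uV)."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EDFFormatError(f"{path}: file too short to be EDF")
        version = head[0:8].decode("ascii", errors="replace").strip()
        if version != "0":
            raise EDFFormatError(
                f"{path}: not an EDF file (version field {version!r})"
            )
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise EDFFormatError(f"{path}: malformed EDF header: {exc}") from exc

        sig_head = fh.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise EDFFormatError(f"{path}: truncated signal headers")

        # offsets within the signal header block; each field is stored
        # contiguously for all ns signals
        off = {}
        cursor = 0
        for name, width in [
            ("label", 16),
            ("transducer", 80),
            ("dim", 8),
            ("pmin", 8),
            ("pmax", 8),
            ("dmin", 8),
            ("dmax", 8),
            ("prefilter", 80),
            ("spr", 8),
        ]:
            off[name] = (cursor, width)
            cursor += width * ns

        def sfield(name, i):
            start, width = off[name]
            return sig_head[start + i * width : start + (i + 1) * width].decode(
                "ascii"
            ).strip()

        labels = [sfield("label", i) for i in range(ns)]
        pmin = [float(sfield("pmin", i)) for i in range(ns)]
        pmax = [float(sfield("pmax", i)) for i in range(ns)]
        dmin = [int(sfield("dmin", i)) for i in range(ns)]
        dmax = [int(sfield("dmax", i)) for i in range(ns)]
        spr = [int(sfield("spr", i)) for i in range(ns)]

        data = fh.read()

    rec_size = sum(spr) * 2
    if n_records < 0:
        n_records = len(data) // rec_size
    if len(data) < n_records * rec_size:
        raise EDFFormatError(f"{path}: truncated data records")

    raw = np.frombuffer(data[: n_records * rec_size], dtype="<i2")
    per_rec = np.reshape(raw, (n_records, sum(spr)))
    traces = {}
    col = 0
    for i, lab in enumerate(labels):
        dig = per_rec[:, col : col + spr[i]].reshape(-1).astype(np.float64)
        col += spr[i]
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        samples = (dig - dmin[i]) * gain + pmin[i]
        fs = spr[i] / record_dur
        traces[lab] = SignalTrace(samples=samples, fs=fs, label=lab)

    return Recording(
        traces=traces,
        duration_s=n_records * record_dur,
        meta={"source": str(path), "record_duration_s": record_dur},
    )
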