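"""Minimal EDF (European Data Format) reader/writer for single-session recordings.

Implements the plain 16-bit EDF layout: a 256-byte ASCII global header,
one 256-byte ASCII header per channel, then fixed-length data records of
little-endian int16 samples scaled linearly between the digital and
physical ranges.  Only uniform-rate continuous recordings are supported,
which is all this package produces or consumes.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


@dataclass
class EdfChannel:
    label: str
    fs: float
    samples: np.ndarray  # physical units
    physical_dim: str = ""


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


_MAX_RECORD_SAMPLES = 30720  # keep records at/below the conventional 61440 bytes


def _record_layout(channels: list[EdfChannel]) -> tuple[int, float, list[int]]:
    """Pick a record count that divides every channel's samples exactly.

    Returns ``(n_records, record_duration, samples_per_record)``; using
    an exact divisor avoids padding the final record, so the file round
    trips to the original length.
    """
    counts = [len(ch.samples) for ch in channels]
    g = counts[0]
    for c in counts[1:]:
        g = math.gcd(g, c)
    duration = counts[0] / channels[0].fs
    k0 = max(1, math.ceil(max(counts) / _MAX_RECORD_SAMPLES))
    for k in range(k0, g + 1):
        if g % k == 0 and max(counts) // k <= _MAX_RECORD_SAMPLES:
            return k, duration / k, [c // k for c in counts]
    # no exact layout (e.g. prime length): one sample per record
    return g, duration / g, [c // g for c in counts]


def write_edf(path, channels: list[EdfChannel]) -> None:
    """Write channels to ``path`` as 16-bit EDF.

    All channels must share a duration; each is quantized over its own
    physical min/max, so the round-trip error is at most half of
    ``(max - min) / 65535`` per channel.
    """
    if not channels:
        raise ValueError("write_edf: no channels given")
    durations = {round(len(ch.samples) / ch.fs, 6) for ch in channels}
    if len(durations) != 1:
        raise ValueError("write_edf: channels have unequal durations")
    ns = len(channels)
    n_records, record_duration, spr = _record_layout(channels)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("recording", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + ns)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field(f"{record_duration:.7g}", 8),
            _field(str(ns), 4),
        ]
    )

    phys_min, phys_max, scale = [], [], []
    for ch in channels:
        lo = float(np.min(ch.samples))
        hi = float(np.max(ch.samples))
        if hi <= lo:  # constant channel: widen to a valid range
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        scale.append((hi - lo) / (_DIG_MAX - _DIG_MIN))

    per_channel = b"".join(
        [
            b"".join(_field(ch.label, 16) for ch in channels),
            b"".join(_field("", 80) for _ in channels),
            b"".join(_field(ch.physical_dim, 8) for ch in channels),
            b"".join(_field(f"{phys_min[i]:.6g}", 8) for i in range(ns)),
            b"".join(_field(f"{phys_max[i]:.6g}", 8) for i in range(ns)),
            b"".join(_field(str(_DIG_MIN), 8) for _ in channels),
            b"".join(_field(str(_DIG_MAX), 8) for _ in channels),
            b"".join(_field("", 80) for _ in channels),
            b"".join(_field(str(n), 8) for n in spr),
            b"".join(_field("", 32) for _ in channels),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header + per_channel)
        for rec in range(n_records):
            for i, ch in enumerate(channels):
                seg = ch.samples[rec * spr[i] : (rec + 1) * spr[i]]
                if len(seg) < spr[i]:  # pad the final partial record
                    seg = np.concatenate(
                        [seg, np.full(spr[i] - len(seg), phys_min[i])]
                    )
                dig = np.round((seg - phys_min[i]) / scale[i]) + _DIG_MIN
                fh.write(dig.astype("<i2").tobytes())


def read_edf(path) -> list[EdfChannel]:
    """Read a 16-bit EDF file written by :func:`write_edf` or any plain EDF."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_records = int(head[236:244].decode("ascii").strip())
        record_duration = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())

        def fields(width):
            raw = fh.read(width * ns)
            return [
                raw[i * width : (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels = fields(16)
        fields(80)  # transducer
        dims = fields(8)
        pmin = [float(v) for v in fields(8)]
        pmax = [float(v) for v in fields(8)]
        dmin = [int(v) for v in fields(8)]
        dmax = [int(v) for v in fields(8)]
        fields(80)  # prefiltering
        spr = [int(v) for v in fields(8)]
        fields(32)  # reserved

        buffers: list[list[np.ndarray]] = [[] for _ in range(ns)]
        for _ in range(n_records):
            for i in range(ns):
                raw = np.frombuffer(fh.read(2 * spr[i]), dtype="<i2")
                buffers[i].append(raw)

    out = []
    for i in range(ns):
        dig = np.concatenate(buffers[i]).astype(float)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        out.append(
            EdfChannel(
                label=labels[i],
                fs=spr[i] / record_duration,
                samples=pmin[i] + (dig - dmin[i]) * gain,
                physical_dim=dims[i],
            )
        )
    return out
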