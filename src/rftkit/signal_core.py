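"""Core domain types, signal I/O and session configuration.

Conventions used throughout the package: times are in seconds, RR/PP
intervals in milliseconds, sample indexing is 0-based and windows are
half-open ``[start, stop)``.  ECG amplitudes are in mV; PPG and
respiration channels carry arbitrary units.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf

__all__ = [
    "SignalKind",
    "BeatKind",
    "IntervalKind",
    "TimeSeriesSignal",
    "BeatSeries",
    "IntervalSeries",
    "SessionConfig",
    "read_signal",
    "write_signal",
    "segment",
    "write_report",
    "read_report",
]


class SignalKind(str, enum.Enum):
    ECG = "ECG"
    PPG = "PPG"
    RESP = "RESP"


class BeatKind(str, enum.Enum):
    R_PEAK = "R_PEAK"
    PULSE_PEAK = "PULSE_PEAK"


class IntervalKind(str, enum.Enum):
    RR = "RR"
    PP = "PP"


#: minimum spacing between detected beats, s
REFRACTORY_S = 0.2

#: physiological RR/PP acceptance window after artifact rejection, ms
INTERVAL_BOUNDS_MS = (200.0, 3000.0)


@dataclass(frozen=True)
class TimeSeriesSignal:
    """A uniformly sampled physiological channel.

    Parameters
    ----------
    samples : array of float
        Signal values (mV for ECG; arbitrary units otherwise).
    fs : float
        Sampling rate, Hz.  Must be positive.
    kind : SignalKind
    t0 : float
        Start time of the first sample, s.
    units : str
        Informational unit string; carried, never converted.
    """

    samples: np.ndarray
    fs: float
    kind: SignalKind
    t0: float = 0.0
    units: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            bad = int(np.flatnonzero(~np.isfinite(samples))[0])
            raise ValueError(f"non-finite sample at index {bad}")

    @property
    def duration(self) -> float:
        """Record length in seconds (number of samples over fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def replace_samples(self, samples: np.ndarray) -> "TimeSeriesSignal":
        return TimeSeriesSignal(samples, self.fs, self.kind, self.t0, self.units)


@dataclass(frozen=True)
class BeatSeries:
    """Detected beat event times, strictly increasing, in seconds.

    Detectors guarantee gaps of at least the refractory period; series
    built from external annotations may still contain closer (spurious)
    events, which interval-series construction rejects.
    """

    event_times: np.ndarray
    kind: BeatKind
    warning: str | None = None

    def __post_init__(self):
        t = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", t)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.event_times.size


@dataclass(frozen=True)
class IntervalSeries:
    """RR or PP interval sequence in ms, after artifact rejection.

    ``end_times`` optionally carries the time (s) of the beat ending each
    interval, so spectral analysis can place intervals on the time axis
    even after artifact rejection has removed some of them.
    """

    intervals: np.ndarray
    kind: IntervalKind
    n_rejected: int = 0
    end_times: np.ndarray | None = None

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", iv)
        if self.end_times is not None:
            t = np.asarray(self.end_times, dtype=float)
            if t.shape != iv.shape:
                raise ValueError("end_times must match intervals in length")
            object.__setattr__(self, "end_times", t)
        lo, hi = INTERVAL_BOUNDS_MS
        if iv.size and (iv.min() <= lo or iv.max() >= hi):
            raise ValueError(f"intervals must lie in ({lo:g}, {hi:g}) ms")

    def __len__(self) -> int:
        return self.intervals.size


@dataclass
class SessionConfig:
    """Configuration of one biofeedback session."""

    fs: float = 512.0
    channels: tuple = (SignalKind.ECG, SignalKind.RESP)
    epoch_length: float = 300.0
    sweep_frequencies: tuple = tuple(np.arange(4.0, 7.01, 0.5))
    seed: int = 0

    def __post_init__(self):
        for f in self.sweep_frequencies:
            if not 4.0 <= f <= 7.0:
                raise ValueError(
                    f"sweep frequency {f} b/min outside the 4-7 b/min range"
                )

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("fs", "epoch_length", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "channels" in raw:
            kwargs["channels"] = tuple(SignalKind(c) for c in raw["channels"])
        if "sweep_frequencies" in raw:
            kwargs["sweep_frequencies"] = tuple(float(f) for f in raw["sweep_frequencies"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# file I/O


def read_signal(path, format: str | None = None, kind: SignalKind = SignalKind.ECG,
                fs: float | None = None) -> TimeSeriesSignal:
    """Read a single-channel signal from CSV or EDF.

    CSV files carry either a ``time_s,value`` pair of columns (fs inferred
    from the time column) or a single ``value`` column, in which case
    ``fs`` must be given.  For EDF, the channel whose label matches
    ``kind`` is returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    if format is None:
        format = "EDF" if path.suffix.lower() == ".edf" else "CSV"
    format = format.upper()

    if format == "CSV":
        frame = pd.read_csv(path)
        cols = [c.strip() for c in frame.columns]
        frame.columns = cols
        if "value" not in cols:
            raise ValueError(f"{path}: expected a 'value' column, found {cols}")
        values = frame["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            raise ValueError(f"{path}: non-finite value in row {bad}")
        t0 = 0.0
        if "time_s" in cols:
            t = frame["time_s"].to_numpy(dtype=float)
            if len(t) < 2:
                raise ValueError(f"{path}: need >= 2 rows to infer fs from time_s")
            dt = np.diff(t)
            if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-5, atol=1e-9):
                raise ValueError(f"{path}: time_s column is not uniformly increasing")
            fs_inferred = 1.0 / dt[0]
            if fs is not None and not math.isclose(fs, fs_inferred, rel_tol=1e-6):
                raise ValueError(
                    f"{path}: fs flag {fs} disagrees with time column ({fs_inferred:g})"
                )
            fs = fs_inferred
            t0 = float(t[0])
        if fs is None:
            raise ValueError(
                f"{path}: sampling rate absent — no time_s column and no fs given"
            )
        return TimeSeriesSignal(values, fs, kind, t0=t0)

    if format == "EDF":
        channels = _edf.read_edf(path)
        for ch in channels:
            if ch.label.upper().startswith(kind.value):
                return TimeSeriesSignal(ch.samples, ch.fs, kind, units=ch.physical_dim)
        raise ValueError(
            f"{path}: no channel labelled {kind.value} "
            f"(found {[c.label for c in channels]})"
        )

    raise ValueError(f"unknown signal format {format!r}")


def write_signal(signal: TimeSeriesSignal, path, format: str | None = None) -> None:
    """Write a signal as two-column CSV (``time_s,value``) or 16-bit EDF."""
    path = Path(path)
    if format is None:
        format = "EDF" if path.suffix.lower() == ".edf" else "CSV"
    format = format.upper()
    if format == "CSV":
        pd.DataFrame({"time_s": signal.times, "value": signal.samples}).to_csv(
            path, index=False, float_format="%.17g"
        )
    elif format == "EDF":
        _edf.write_edf(
            path,
            [
                _edf.EdfChannel(
                    label=signal.kind.value,
                    fs=signal.fs,
                    samples=signal.samples,
                    physical_dim=signal.units,
                )
            ],
        )
    else:
        raise ValueError(f"unknown signal format {format!r}")


def segment(signal: TimeSeriesSignal, start: float, stop: float) -> TimeSeriesSignal:
    """Return the half-open window ``[start, stop)`` seconds relative to t0."""
    if not (0 <= start < stop <= signal.duration + 1e-12):
        raise ValueError(
            f"invalid window [{start}, {stop}) for a {signal.duration:g} s signal"
        )
    i0 = int(round(start * signal.fs))
    i1 = int(round(stop * signal.fs))
    if i1 <= i0:
        raise ValueError(f"empty window [{start}, {stop})")
    return TimeSeriesSignal(
        signal.samples[i0:i1], signal.fs, signal.kind,
        t0=signal.t0 + i0 / signal.fs, units=signal.units,
    )


# ---------------------------------------------------------------------------
# reports


def _to_jsonable(obj):
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(report: dict, path, format: str = "JSON") -> None:
    """Serialize an analysis report at full numeric precision."""
    if not report:
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    payload = _to_jsonable(report)
    format = format.upper()
    if format == "JSON":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "CSV":
        flat = pd.json_normalize(payload, sep=".")
        flat.T.reset_index().to_csv(path, index=False, header=["key", "value"])
    elif format == "TXT":
        lines = [f"{k}: {v}" for k, v in sorted(_flatten(payload).items())]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def _flatten(d, prefix=""):
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
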