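"""Time-domain, frequency-domain, coherence and respiratory summary metrics.

Frequency analysis follows the standard short-term HRV recipe: the RR
tachogram is resampled onto a uniform 4 Hz grid with cubic
interpolation, linearly detrended, and its power spectral density
estimated by Welch's method (120 s Hann segments, 50% overlap).  Band
powers use the conventional short-term bands — total power up to
0.4 Hz, LF 0.04-0.15 Hz, HF 0.15-0.4 Hz — with normalized units defined
as a percentage of LF+HF power, so lf_nu + hf_nu = 100 by construction.

The coherence ratio (CR) quantifies how sine-wave-like the heart rhythm
is: the power in a 0.030 Hz window around the tallest spectral peak in
0.04-0.26 Hz, divided by the remaining power.  A paced, resonant rhythm
concentrates nearly all variability in that window and scores high; an
erratic rhythm spreads power across the band and scores low.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import interpolate, signal as sps

from .detectors import RespCycleSeries
from .signal_core import IntervalSeries

__all__ = [
    "Spectrum",
    "HRVMetrics",
    "RespStats",
    "sdnn",
    "rmssd",
    "rr_psd",
    "band_powers",
    "normalized_units",
    "coherence_ratio",
    "resp_stats",
    "compute_hrv_metrics",
]

RESAMPLE_FS = 4.0      # Hz, uniform tachogram grid
WELCH_SEGMENT_S = 120.0
TP_BAND = (0.0, 0.4)   # Hz
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
CR_SEARCH_BAND = (0.04, 0.26)
CR_WINDOW_HZ = 0.030


@dataclass(frozen=True)
class Spectrum:
    """One-sided PSD of the resampled RR tachogram, ms^2/Hz."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f[0] != 0 or not np.allclose(np.diff(f), f[1] - f[0]):
            raise ValueError("frequency grid must start at 0 and be uniform")
        if np.any(p < 0):
            raise ValueError("power densities must be non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class HRVMetrics:
    sdnn: float        # ms
    rmssd: float       # ms
    tp: float          # ms^2
    lf_abs: float      # ms^2
    hf_abs: float      # ms^2
    lf_nu: float       # % of LF+HF
    hf_nu: float       # % of LF+HF
    lf_hf: float       # ratio
    cr: float          # coherence ratio

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RespStats:
    breathing_rate: float  # breaths/min
    mean_insp: float       # s
    mean_exp: float        # s

    def to_dict(self) -> dict:
        return asdict(self)


def _values(intervals) -> np.ndarray:
    if isinstance(intervals, IntervalSeries):
        return intervals.intervals
    return np.asarray(intervals, dtype=float)


def sdnn(intervals) -> float:
    """Standard deviation of all intervals, ms (sample SD, n-1 denominator)."""
    iv = _values(intervals)
    if len(iv) < 2:
        raise ValueError(f"SDNN needs >= 2 intervals, got {len(iv)}")
    return float(np.std(iv, ddof=1))


def rmssd(intervals) -> float:
    """Root mean square of successive interval differences, ms."""
    iv = _values(intervals)
    if len(iv) < 3:
        raise ValueError(f"rMSSD needs >= 3 intervals, got {len(iv)}")
    d = np.diff(iv)
    return float(np.sqrt(np.mean(d * d)))


def rr_psd(intervals, beat_times=None, resample_fs: float = RESAMPLE_FS) -> Spectrum:
    """Welch PSD of the RR tachogram on a uniform grid.

    ``beat_times`` are the times (s) of the beats ending each interval;
    omitted, they are taken from ``intervals.end_times``.  Requires at
    least 2 minutes of data.
    """
    iv = _values(intervals)
    if beat_times is None:
        if not isinstance(intervals, IntervalSeries) or intervals.end_times is None:
            raise ValueError("beat_times required when intervals carry no end_times")
        beat_times = intervals.end_times
    t = np.asarray(beat_times, dtype=float)
    if t.shape != iv.shape:
        raise ValueError("beat_times must have one entry per interval")
    span = t[-1] - t[0]
    if span < 120.0:
        raise ValueError(f"spectral analysis needs >= 2 min of beats, got {span:g} s")
    grid = np.arange(t[0], t[-1], 1.0 / resample_fs)
    rr_t = interpolate.interp1d(t, iv, kind="cubic")(grid)
    rr_t = sps.detrend(rr_t, type="linear")
    nperseg = min(len(rr_t), int(WELCH_SEGMENT_S * resample_fs))
    freqs, power = sps.welch(
        rr_t, fs=resample_fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )
    return Spectrum(freqs, power)


def _band_integral(spec: Spectrum, lo: float, hi: float) -> float:
    """Exact trapezoidal integral of the piecewise-linear PSD over [lo, hi]."""
    f, p = spec.freqs, spec.power
    lo = max(lo, f[0])
    hi = min(hi, f[-1])
    if hi <= lo:
        return 0.0
    inner = (f > lo) & (f < hi)
    xs = np.concatenate([[lo], f[inner], [hi]])
    ys = np.concatenate([[np.interp(lo, f, p)], p[inner], [np.interp(hi, f, p)]])
    return float(np.trapezoid(ys, xs))


def band_powers(spec: Spectrum) -> tuple[float, float, float]:
    """(total, LF, HF) band powers in ms^2 by trapezoidal integration."""
    if spec.freqs[-1] < TP_BAND[1]:
        raise ValueError(f"spectrum must extend to {TP_BAND[1]} Hz")
    if spec.df > 0.01:
        raise ValueError(
            f"frequency resolution {spec.df:g} Hz too coarse (need <= 0.01 Hz)"
        )
    tp = _band_integral(spec, *TP_BAND)
    lf = _band_integral(spec, *LF_BAND)
    hf = _band_integral(spec, *HF_BAND)
    return tp, lf, hf


def normalized_units(lf_abs: float, hf_abs: float) -> tuple[float, float, float]:
    """LF and HF as percentages of LF+HF, plus their ratio.

    ``lf_nu = 100*LF/(LF+HF)``; ``hf_nu = 100 - lf_nu``;
    ``lf_hf = LF/HF`` (reported as ``inf`` when HF is zero).
    """
    if lf_abs < 0 or hf_abs < 0:
        raise ValueError("band powers must be non-negative")
    total = lf_abs + hf_abs
    if total <= 0:
        raise ValueError("LF + HF power is zero; normalized units undefined")
    lf_nu = 100.0 * lf_abs / total
    hf_nu = 100.0 - lf_nu
    lf_hf = lf_abs / hf_abs if hf_abs > 0 else float("inf")
    return lf_nu, hf_nu, lf_hf


def coherence_ratio(spec: Spectrum) -> float:
    """Peak-window power over remaining power.

    Locates the maximum PSD value in the 0.04-0.26 Hz search band,
    integrates the PSD over a 0.030 Hz window centred on it (P), and
    returns ``P / (TP - P)`` where TP is the total power up to 0.4 Hz.
    """
    tp = _band_integral(spec, *TP_BAND)
    if tp <= 0:
        raise ValueError("total power is zero; coherence ratio undefined")
    mask = (spec.freqs >= CR_SEARCH_BAND[0]) & (spec.freqs <= CR_SEARCH_BAND[1])
    if not np.any(mask):
        raise ValueError("spectrum does not cover the 0.04-0.26 Hz search band")
    f_peak = spec.freqs[mask][np.argmax(spec.power[mask])]
    half = CR_WINDOW_HZ / 2.0
    p = _band_integral(spec, f_peak - half, f_peak + half)
    if p >= tp:
        return float("inf")
    return float(p / (tp - p))


def resp_stats(cycles: RespCycleSeries) -> RespStats:
    """Breathing rate (60 / mean cycle length) and mean inspiration/expiration."""
    if cycles.n_cycles < 2:
        raise ValueError(f"need >= 2 complete cycles, got {cycles.n_cycles}")
    mean_cycle = float(np.mean(cycles.cycle_lengths))
    return RespStats(
        breathing_rate=60.0 / mean_cycle,
        mean_insp=float(np.mean(cycles.insp_durations)),
        mean_exp=float(np.mean(cycles.exp_durations)),
    )


def compute_hrv_metrics(intervals, beat_times=None) -> HRVMetrics:
    """All Table-style HRV variables from one interval series."""
    spec = rr_psd(intervals, beat_times)
    tp, lf, hf = band_powers(spec)
    lf_nu, hf_nu, lf_hf = normalized_units(lf, hf)
    return HRVMetrics(
        sdnn=sdnn(intervals),
        rmssd=rmssd(intervals),
        tp=tp,
        lf_abs=lf,
        hf_abs=hf,
        lf_nu=lf_nu,
        hf_nu=hf_nu,
        lf_hf=lf_hf,
        cr=coherence_ratio(spec),
    )
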