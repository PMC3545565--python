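"""Event detection: adaptive-threshold beat detection and breath segmentation.

The beat detector follows the classic integrate-and-threshold design:
band-pass to the QRS energy band, differentiate, square, integrate over
a moving window, then walk the integrated envelope's local maxima with
an adaptively updated threshold, a refractory period, and a search-back
pass for beats missed during threshold adaptation.  Candidate times are
refined to the raw-signal maximum so reported R-peak times are
amplitude-accurate.  The same machinery detects PPG pulse peaks with a
lower analysis band and a wider refinement window.

Breath segmentation finds alternating troughs and peaks on a smoothed
respiration trace; rising segments (trough to peak) are inspiration.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .preprocess import _zero_phase_fir, _odd
from .signal_core import (
    BeatKind,
    BeatSeries,
    IntervalKind,
    IntervalSeries,
    INTERVAL_BOUNDS_MS,
    REFRACTORY_S,
    SignalKind,
    TimeSeriesSignal,
)

__all__ = [
    "detect_r_peaks",
    "detect_pulse_peaks",
    "detect_resp_cycles",
    "beats_to_intervals",
    "detection_rate",
    "RespCycleSeries",
]

#: adaptive threshold = ALPHA * running peak estimate
ALPHA = 0.5
#: exponential update weight of a newly accepted peak
PEAK_UPDATE = 0.125
#: search-back is triggered after this multiple of the running mean RR
SEARCHBACK_FACTOR = 1.66
#: moving-window integration length, s
INTEGRATION_WINDOW_S = 0.150


class RespCycleSeries:
    """Per-breath trough/peak times with inspiration/expiration durations.

    Troughs and peaks must alternate strictly; only complete cycles
    (trough -> peak -> next trough) are kept, so ``insp_durations`` and
    ``exp_durations`` have one entry per complete breath.
    """

    def __init__(self, trough_times, peak_times):
        troughs = np.asarray(trough_times, dtype=float)
        peaks = np.asarray(peak_times, dtype=float)
        if len(peaks) != len(troughs) - 1:
            raise ValueError(
                "expected one peak between each pair of troughs "
                f"(got {len(troughs)} troughs, {len(peaks)} peaks)"
            )
        merged = np.empty(len(troughs) + len(peaks))
        merged[0::2] = troughs
        merged[1::2] = peaks
        if np.any(np.diff(merged) <= 0):
            raise ValueError("troughs and peaks must alternate strictly in time")
        self.trough_times = troughs
        self.peak_times = peaks

    @property
    def n_cycles(self) -> int:
        return len(self.peak_times)

    @property
    def cycle_lengths(self) -> np.ndarray:
        """Trough-to-trough breath durations, s."""
        return np.diff(self.trough_times)

    @property
    def insp_durations(self) -> np.ndarray:
        return self.peak_times - self.trough_times[:-1]

    @property
    def exp_durations(self) -> np.ndarray:
        return self.trough_times[1:] - self.peak_times


def _envelope(sig: TimeSeriesSignal, band: tuple[float, float]) -> np.ndarray:
    """Band-pass -> differentiate -> square -> moving-window integrate."""
    fs = sig.fs
    numtaps = _odd(min(3.3 * fs / 2.0, len(sig.samples) - 2))
    taps = sps.firwin(numtaps, band, pass_zero=False, fs=fs)
    filtered = _zero_phase_fir(sig.samples - sig.samples.mean(), taps)
    diff = np.gradient(filtered) * fs
    squared = diff * diff
    win = _odd(INTEGRATION_WINDOW_S * fs)
    return _zero_phase_fir(squared, np.full(win, 1.0 / win))


def _refine_to_raw(raw: np.ndarray, idx: int, half_window: int) -> int:
    lo = max(0, idx - half_window)
    hi = min(len(raw), idx + half_window + 1)
    return lo + int(np.argmax(raw[lo:hi]))


def _adaptive_threshold_pass(env: np.ndarray, fs: float) -> list[int]:
    """Walk envelope local maxima with the adaptive threshold update.

    Threshold: thr = ALPHA * rpe, with the running peak estimate updated
    per accepted beat as rpe <- PEAK_UPDATE*peak + (1-PEAK_UPDATE)*rpe.
    If no beat is accepted for SEARCHBACK_FACTOR times the running mean
    RR, the largest rejected candidate in the gap above thr/2 is
    accepted retroactively.
    """
    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(env, distance=refractory)
    if cand.size == 0:
        return []
    # seed the running estimate from the first two seconds of envelope peaks
    lead = cand[cand < int(2 * fs)]
    rpe = float(np.max(env[lead])) if lead.size else float(np.max(env[cand]))
    accepted: list[int] = []
    rejected: list[int] = []
    rr_history: list[float] = []

    def mean_rr() -> float:
        return float(np.mean(rr_history[-8:])) if rr_history else 1.0

    for idx in cand:
        thr = ALPHA * rpe
        if env[idx] >= thr:
            if accepted and idx - accepted[-1] < refractory:
                continue
            # search-back: did we skip a beat inside a long gap?
            if accepted and (idx - accepted[-1]) > SEARCHBACK_FACTOR * mean_rr() * fs:
                gap = [j for j in rejected if accepted[-1] + refractory < j < idx - refractory]
                if gap:
                    best = max(gap, key=lambda j: env[j])
                    if env[best] >= 0.5 * thr:
                        rr_history.append((best - accepted[-1]) / fs)
                        accepted.append(best)
            if accepted:
                rr_history.append((idx - accepted[-1]) / fs)
            accepted.append(idx)
            rpe = PEAK_UPDATE * float(env[idx]) + (1 - PEAK_UPDATE) * rpe
        else:
            rejected.append(idx)
    return accepted


def _detect_beats(sig: TimeSeriesSignal, band, refine_s, kind: BeatKind) -> BeatSeries:
    if sig.duration < 5.0:
        raise ValueError(f"need >= 5 s of signal, got {sig.duration:g} s")
    env = _envelope(sig, band)
    if np.max(env) <= 0:
        return BeatSeries(np.array([]), kind, warning="no candidate beats found")
    idx = _adaptive_threshold_pass(env, sig.fs)
    if not idx:
        return BeatSeries(np.array([]), kind, warning="no candidate beats found")
    half = int(round(refine_s * sig.fs))
    refined = sorted({_refine_to_raw(sig.samples, i, half) for i in idx})
    # refinement can merge neighbours; enforce the refractory gap
    keep = [refined[0]]
    for i in refined[1:]:
        if i - keep[-1] >= int(REFRACTORY_S * sig.fs):
            keep.append(i)
    times = sig.t0 + np.asarray(keep, dtype=float) / sig.fs
    return BeatSeries(times, kind)


def detect_r_peaks(ecg: TimeSeriesSignal) -> BeatSeries:
    """Detect R-peaks on a preprocessed ECG.

    Analysis band 5-15 Hz (QRS energy); candidate times refined to the
    raw-ECG maximum within +/-50 ms.  Returns an empty series with a
    warning flag when the record contains no candidates at all.
    """
    if ecg.fs < 128:
        raise ValueError(f"R-peak detection needs fs >= 128 Hz, got {ecg.fs}")
    return _detect_beats(ecg, (5.0, 15.0), 0.050, BeatKind.R_PEAK)


def detect_pulse_peaks(ppg: TimeSeriesSignal) -> BeatSeries:
    """Detect pulse peaks on a preprocessed PPG (band 0.5-8 Hz, +/-100 ms refine)."""
    return _detect_beats(ppg, (0.5, 8.0), 0.100, BeatKind.PULSE_PEAK)


def detect_resp_cycles(resp: TimeSeriesSignal, min_cycle_s: float = 1.5,
                       invert: bool = False) -> RespCycleSeries:
    """Segment a respiration trace into breaths.

    The trace is smoothed with a 1 s moving average; alternating local
    extrema with prominence of at least 20% of the inter-quartile range
    and spacing of at least ``min_cycle_s`` are kept, and each extremum
    is refined to the raw-signal extremum nearby so asymmetric breath
    shapes are timed correctly.  Rising segments are inspiration; pass
    ``invert=True`` for sensors whose output falls during inspiration.
    """
    x = resp.samples.astype(float)
    if invert:
        x = -x
    fs = resp.fs
    win = _odd(1.0 * fs)
    if win >= len(x):
        raise ValueError("respiration record too short to smooth")
    smooth = _zero_phase_fir(x, np.full(win, 1.0 / win))
    q75, q25 = np.percentile(smooth, [75, 25])
    prom = 0.2 * (q75 - q25)
    dist = max(1, int(min_cycle_s * fs))
    peaks, _ = sps.find_peaks(smooth, prominence=prom, distance=dist)
    troughs, _ = sps.find_peaks(-smooth, prominence=prom, distance=dist)
    if len(peaks) < 2 or len(troughs) < 2:
        raise ValueError("fewer than 2 complete respiratory cycles detected")

    # refine to raw extrema within half a smoothing window
    half = win // 2
    peaks = np.array([_refine_to_raw(x, p, half) for p in peaks])
    troughs = np.array([_refine_to_raw(-x, t, half) for t in troughs])

    # keep a strict trough-peak-trough alternation: for each pair of
    # consecutive troughs keep the highest peak in between
    kept_troughs = [troughs[0]]
    kept_peaks = []
    for t in troughs[1:]:
        inside = peaks[(peaks > kept_troughs[-1]) & (peaks < t)]
        if inside.size == 0:
            continue  # no peak between troughs: skip the later trough
        kept_peaks.append(inside[np.argmax(x[inside])])
        kept_troughs.append(t)
    if len(kept_peaks) < 2:
        raise ValueError("fewer than 2 complete respiratory cycles detected")
    t_arr = resp.t0 + np.asarray(kept_troughs) / fs
    p_arr = resp.t0 + np.asarray(kept_peaks) / fs
    return RespCycleSeries(t_arr, p_arr)


def detection_rate(detected: BeatSeries, truth_times, window_s: float = 0.05) -> float:
    """Fraction of true events matched one-to-one within ``window_s``."""
    truth = np.asarray(truth_times, dtype=float)
    if truth.size == 0:
        raise ValueError("no true events to match against")
    det = detected.event_times
    if det.size == 0:
        return 0.0
    used = np.zeros(det.size, dtype=bool)
    matched = 0
    for t in truth:
        d = np.abs(det - t)
        i = int(np.argmin(d))
        if d[i] <= window_s and not used[i]:
            used[i] = True
            matched += 1
    return matched / truth.size


def beats_to_intervals(beats: BeatSeries, median_window: int = 11,
                       tolerance: float = 0.30) -> IntervalSeries:
    """Convert beat times to an artifact-rejected interval series in ms.

    Rejection rules, applied per interval against the median of the
    surrounding ``median_window`` intervals:

    - outside the physiological (200, 3000) ms range;
    - deviating from the local median by more than ``tolerance``;
    - the partner of a sub-200 ms interval when the two sum to within
      ``tolerance`` of the local median — a spurious beat splits one
      true interval into two sub-intervals, and neither half is a real
      cardiac interval.
    """
    if len(beats) < 3:
        raise ValueError(f"need >= 3 beat events, got {len(beats)}")
    iv = np.diff(beats.event_times) * 1000.0
    n = len(iv)
    lo, hi = INTERVAL_BOUNDS_MS
    half = median_window // 2
    local_med = np.array([
        np.median(iv[max(0, i - half): min(n, i + half + 1)]) for i in range(n)
    ])
    drop = np.zeros(n, dtype=bool)
    drop |= (iv <= lo) | (iv >= hi)
    drop |= np.abs(iv - local_med) > tolerance * local_med
    for i in np.flatnonzero(iv <= lo):
        # drop the neighbour whose sum with the short interval best
        # reconstructs a plausible local interval (the split partner)
        candidates = [j for j in (i - 1, i + 1) if 0 <= j < n and not drop[j]]
        if not candidates:
            continue
        j = min(candidates, key=lambda k: abs(iv[i] + iv[k] - local_med[i]))
        if abs(iv[i] + iv[j] - local_med[i]) <= tolerance * local_med[i]:
            drop[j] = True
    kept = iv[~drop]
    if len(kept) < 2:
        raise ValueError("fewer than 2 intervals survive artifact rejection")
    kind = IntervalKind.RR if beats.kind is BeatKind.R_PEAK else IntervalKind.PP
    return IntervalSeries(kept, kind, n_rejected=int(drop.sum()),
                          end_times=beats.event_times[1:][~drop])
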