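"""Resonance-frequency training: the three-step biofeedback procedure.

Step 1 sweeps paced breathing across 4-7 breaths/min in 0.5 b/min
increments and picks the frequency at which the RSA gain — the mean
per-breath peak-to-trough RR excursion — is largest.  Step 2 assesses
stress from the session's HRV metrics.  Step 3 is paced-breathing
training at the resonant frequency, tracked by pacing adherence and
pre/post metric comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detectors import RespCycleSeries
from .hrv_metrics import HRVMetrics, compute_hrv_metrics
from .signal_core import IntervalSeries, SessionConfig, SignalKind, TimeSeriesSignal
from .stress_assessment import StressAssessment, assess

__all__ = [
    "SweepEpoch",
    "ResonanceSweepResult",
    "SessionReport",
    "rsa_amplitude",
    "pacing_waveform",
    "resonance_sweep",
    "run_biofeedback_session",
]

SWEEP_RANGE = (4.0, 7.0)  # breaths/min
MIN_EPOCH_S = 120.0


@dataclass
class SweepEpoch:
    """One paced-breathing measurement epoch of the resonance sweep."""

    pacing_frequency: float           # breaths/min
    rr: IntervalSeries
    beat_times: np.ndarray
    resp: RespCycleSeries | None = None


@dataclass
class ResonanceSweepResult:
    per_frequency_gain: dict          # breaths/min -> ms
    resonant_frequency: float         # breaths/min

    def to_dict(self) -> dict:
        return {
            "per_frequency_gain": {f"{k:g}": v for k, v in self.per_frequency_gain.items()},
            "resonant_frequency": self.resonant_frequency,
        }


@dataclass
class SessionReport:
    pre_metrics: HRVMetrics
    post_metrics: HRVMetrics
    pre_assessment: StressAssessment
    post_assessment: StressAssessment
    resonant_frequency: float
    per_frequency_gain: dict
    adherence: float                  # fraction of breaths at the paced rate

    def to_dict(self) -> dict:
        return {
            "pre_metrics": self.pre_metrics.to_dict(),
            "post_metrics": self.post_metrics.to_dict(),
            "pre_assessment": self.pre_assessment.to_dict(),
            "post_assessment": self.post_assessment.to_dict(),
            "resonant_frequency": self.resonant_frequency,
            "per_frequency_gain": {f"{k:g}": v for k, v in self.per_frequency_gain.items()},
            "adherence": self.adherence,
        }


def _nominal_cycles(beat_times: np.ndarray, pacing_frequency: float) -> RespCycleSeries:
    """Breath windows implied by the pacing guide when no respiration trace exists."""
    period = 60.0 / pacing_frequency
    t0, t1 = beat_times[0], beat_times[-1]
    n = int((t1 - t0) // period)
    troughs = t0 + np.arange(n + 1) * period
    peaks = troughs[:-1] + period / 2.0
    return RespCycleSeries(troughs, peaks)


def rsa_amplitude(rr: IntervalSeries, beat_times, cycles: RespCycleSeries,
                  min_breaths: int = 5, min_beats_per_breath: int = 3) -> float:
    """Mean per-breath peak-to-trough RR excursion, ms.

    For each complete breath (trough-to-trough span), the amplitude is
    max(RR) - min(RR) over the intervals whose ending beat falls inside
    the span; breaths with fewer than ``min_beats_per_breath`` intervals
    are skipped.  Requires at least ``min_breaths`` usable breaths.
    """
    t = np.asarray(beat_times, dtype=float)
    iv = rr.intervals
    if t.shape != iv.shape:
        # beat_times may include the first beat, which ends no interval
        if len(t) == len(iv) + 1:
            t = t[1:]
        else:
            raise ValueError("beat_times must align with intervals")
    amplitudes = []
    for lo, hi in zip(cycles.trough_times[:-1], cycles.trough_times[1:]):
        inside = iv[(t >= lo) & (t < hi)]
        if len(inside) >= min_beats_per_breath:
            amplitudes.append(float(inside.max() - inside.min()))
    if len(amplitudes) < min_breaths:
        raise ValueError(
            f"need >= {min_breaths} breaths with >= {min_beats_per_breath} "
            f"beats each, got {len(amplitudes)}"
        )
    return float(np.mean(amplitudes))


def pacing_waveform(frequency: float, duration: float, fs: float = 64.0) -> TimeSeriesSignal:
    """Raised-cosine breathing guide in [0, 1] with equal inhale/exhale halves."""
    if not SWEEP_RANGE[0] <= frequency <= SWEEP_RANGE[1]:
        raise ValueError(
            f"pacing frequency {frequency} b/min outside {SWEEP_RANGE} b/min"
        )
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(int(round(duration * fs))) / fs
    guide = 0.5 - 0.5 * np.cos(2 * np.pi * (frequency / 60.0) * t)
    return TimeSeriesSignal(guide, fs, SignalKind.RESP, units="guide")


def resonance_sweep(epochs: list[SweepEpoch],
                    grid: tuple = tuple(np.arange(4.0, 7.01, 0.5))) -> ResonanceSweepResult:
    """Pick the breathing frequency with maximal RSA gain.

    Every grid frequency must be covered by exactly one epoch of at
    least 2 minutes.  Ties break toward the lowest frequency (slower
    breathing preferred on equal evidence); the result is independent of
    epoch order.
    """
    by_freq = {}
    for ep in epochs:
        if ep.pacing_frequency in by_freq:
            raise ValueError(f"duplicate epoch for {ep.pacing_frequency} b/min")
        by_freq[ep.pacing_frequency] = ep
    missing = [f for f in grid if f not in by_freq]
    if missing:
        raise ValueError(f"sweep grid frequency missing: {missing[0]:g} b/min")
    gains = {}
    for f in sorted(grid):
        ep = by_freq[f]
        span = ep.beat_times[-1] - ep.beat_times[0]
        if span < MIN_EPOCH_S:
            raise ValueError(
                f"epoch at {f:g} b/min too short: {span:g} s < {MIN_EPOCH_S:g} s"
            )
        cycles = ep.resp if ep.resp is not None else _nominal_cycles(
            np.asarray(ep.beat_times), f
        )
        gains[float(f)] = rsa_amplitude(ep.rr, ep.beat_times, cycles)
    best = min(gains, key=lambda f: (-gains[f], f))
    return ResonanceSweepResult(per_frequency_gain=gains, resonant_frequency=best)


def _adherence(cycles: RespCycleSeries, pacing_frequency: float,
               tolerance_bpm: float = 0.5) -> float:
    rates = 60.0 / cycles.cycle_lengths
    return float(np.mean(np.abs(rates - pacing_frequency) <= tolerance_bpm))


def run_biofeedback_session(config: SessionConfig, signals: dict) -> SessionReport:
    """Execute the three-step protocol on prepared per-stage inputs.

    ``signals`` maps stage names to data:

    - ``"sweep"``: list of :class:`SweepEpoch`, one per grid frequency;
    - ``"pre"``: dict with ``rr`` (IntervalSeries), ``beat_times``;
    - ``"post"``: dict with ``rr``, ``beat_times`` and ``resp``
      (RespCycleSeries) of the training epoch.

    The report is deterministic given the inputs; failures are labelled
    with the protocol step in which they occurred.
    """
    try:
        if "sweep" not in signals:
            raise ValueError("respiration sweep epochs absent")
        sweep = resonance_sweep(signals["sweep"], grid=config.sweep_frequencies)
    except Exception as exc:
        raise RuntimeError(f"step 1 (resonance search) failed: {exc}") from exc

    try:
        pre = signals["pre"]
        pre_metrics = compute_hrv_metrics(pre["rr"], pre.get("beat_times"))
        pre_assessment = assess(pre_metrics)
    except Exception as exc:
        raise RuntimeError(f"step 2 (stress assessment) failed: {exc}") from exc

    try:
        post = signals["post"]
        post_metrics = compute_hrv_metrics(post["rr"], post.get("beat_times"))
        post_assessment = assess(post_metrics)
        if "resp" in post and post["resp"] is not None:
            adherence = _adherence(post["resp"], sweep.resonant_frequency)
        else:
            adherence = float("nan")
    except Exception as exc:
        raise RuntimeError(f"step 3 (training analysis) failed: {exc}") from exc

    return SessionReport(
        pre_metrics=pre_metrics,
        post_metrics=post_metrics,
        pre_assessment=pre_assessment,
        post_assessment=post_assessment,
        resonant_frequency=sweep.resonant_frequency,
        per_frequency_gain=sweep.per_frequency_gain,
        adherence=adherence,
    )
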