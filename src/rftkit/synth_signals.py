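"""Synthetic cardiorespiratory signals with ground-truth annotations.

The generator produces the three channels a wearable biofeedback monitor
records — ECG, PPG and respiration — plus the underlying truth (beat
times, breath segmentation, RR modulation parameters), so every analysis
stage can be tested by parameter recovery.

Heart-rate dynamics use an IPFM-style (integral pulse frequency
modulation) construction: an instantaneous RR trajectory

    RR(t) = mean_rr + 0.5 * gain(f_b) * sin(2*pi*f_b*t) + noise(t)

is integrated as a beat rate, and a beat fires each time the integral
crosses an integer.  Beat times and the RR series therefore stay
mutually consistent by construction.  The RSA gain is a unimodal
function of the breathing frequency peaking at the model's resonance
frequency, emulating the resonance property of the baroreflex loop:
slow paced breathing near ~6 breaths/min (0.1 Hz) yields the largest
heart-rate oscillations.

ECG morphology is a Gaussian-sum template (P, Q, R, S, T waves) — good
enough to exercise detectors, not clinically realistic.  Respiration is
a raised-cosine cycle with a configurable inspiratory fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detectors import RespCycleSeries
from .signal_core import (
    BeatKind,
    BeatSeries,
    IntervalKind,
    IntervalSeries,
    SignalKind,
    TimeSeriesSignal,
)

__all__ = [
    "RSAModel",
    "NoiseSpec",
    "synth_rr",
    "synth_ecg",
    "synth_ppg",
    "synth_resp",
    "make_cohort",
    "DEFAULT_GROUP_PROFILES",
]


@dataclass(frozen=True)
class RSAModel:
    """Heart-rate dynamics of one synthetic subject.

    ``peak_gain`` is the peak-to-trough RR oscillation (ms) elicited by
    breathing exactly at ``resonance_freq``; away from resonance the
    gain falls off as a Gaussian with width ``gain_width`` (b/min).
    ``rr_noise_sd`` adds band-limited Gaussian RR variability on top of
    the deterministic modulation.
    """

    mean_rr: float = 857.0          # ms (~70 bpm)
    resonance_freq: float = 6.0     # breaths/min
    peak_gain: float = 100.0        # ms, peak-to-trough at resonance
    gain_width: float = 0.7         # b/min, Gaussian falloff
    rr_noise_sd: float = 0.0        # ms
    seed: int = 0

    def gain(self, breathing_freq: float) -> float:
        """Unimodal RSA gain curve, maximal at the resonance frequency."""
        if breathing_freq <= 0:
            raise ValueError(f"breathing frequency must be positive, got {breathing_freq}")
        z = (breathing_freq - self.resonance_freq) / self.gain_width
        return self.peak_gain * math.exp(-0.5 * z * z)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise for rendered waveforms; all amplitudes >= 0."""

    powerline_amp: float = 0.0      # amplitude of 60 Hz sine, signal units
    baseline_amp: float = 0.0      # amplitude of slow sinusoidal wander
    baseline_freq: float = 0.3      # Hz (< 0.5)
    impulse_rate: float = 0.0       # events/min
    impulse_amp: float = 0.0        # signal units
    snr_db: float | None = None     # broadband white noise, alternative spec

    def __post_init__(self):
        for name in ("powerline_amp", "baseline_amp", "impulse_rate", "impulse_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def apply(self, samples: np.ndarray, fs: float, rng: np.random.Generator) -> np.ndarray:
        t = np.arange(len(samples)) / fs
        out = samples.copy()
        if self.powerline_amp:
            out += self.powerline_amp * np.sin(2 * np.pi * 60.0 * t)
        if self.baseline_amp:
            out += self.baseline_amp * np.sin(2 * np.pi * self.baseline_freq * t)
        if self.impulse_rate and self.impulse_amp:
            n = rng.poisson(self.impulse_rate * len(samples) / fs / 60.0)
            idx = rng.integers(0, len(samples), size=n)
            out[idx] += self.impulse_amp * rng.choice([-1.0, 1.0], size=n)
        if self.snr_db is not None:
            p_sig = float(np.mean(samples**2))
            p_noise = p_sig / 10 ** (self.snr_db / 10)
            out += rng.normal(0.0, math.sqrt(p_noise), size=len(samples))
        return out


def _smooth_noise(rng, duration, sd, t_eval, knot_rate=0.7):
    """Band-limited Gaussian process: white knots at ``knot_rate`` Hz, cubic-blended."""
    from scipy.interpolate import CubicSpline

    n_knots = max(4, int(duration * knot_rate) + 2)
    knots_t = np.linspace(-1.0, duration + 1.0, n_knots)
    knots_v = rng.normal(0.0, sd, size=n_knots)
    return CubicSpline(knots_t, knots_v)(t_eval)


def synth_rr(model: RSAModel, breathing_freq: float, duration: float,
             rng: np.random.Generator | None = None) -> tuple[IntervalSeries, np.ndarray]:
    """Generate a consistent (interval series, beat times) pair.

    The RR trajectory is sampled on an 8 Hz grid, its reciprocal
    integrated, and beats placed at integer crossings of the integral
    (integrate-to-threshold).  Deterministic given the model seed.
    """
    if duration < 60:
        raise ValueError(f"duration must be >= 60 s, got {duration}")
    gain = model.gain(breathing_freq)
    if rng is None:
        rng = np.random.default_rng(model.seed)
    f_hz = breathing_freq / 60.0
    dt = 1.0 / 8.0
    tgrid = np.arange(0.0, duration + dt, dt)
    rr_t = model.mean_rr + 0.5 * gain * np.sin(2 * np.pi * f_hz * tgrid)
    if model.rr_noise_sd > 0:
        rr_t = rr_t + _smooth_noise(rng, duration, model.rr_noise_sd, tgrid)
    rr_t = np.clip(rr_t, 300.0, 2500.0)
    rate = 1000.0 / rr_t  # beats per second
    phase = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt)])
    n_beats = int(phase[-1])
    beat_times = np.interp(np.arange(1, n_beats + 1), phase, tgrid)
    intervals = np.diff(beat_times) * 1000.0
    series = IntervalSeries(intervals, IntervalKind.RR, end_times=beat_times[1:])
    return series, beat_times


# Gaussian-sum ECG template: (offset s, amplitude mV, width s)
_ECG_WAVES = (
    (-0.20, 0.15, 0.025),   # P
    (-0.025, -0.10, 0.010),  # Q
    (0.0, 1.00, 0.012),      # R
    (0.025, -0.15, 0.010),   # S
    (0.25, 0.30, 0.045),     # T
)


def synth_ecg(beat_times, fs: float = 512.0,
              noise: NoiseSpec | None = None,
              rng: np.random.Generator | None = None,
              duration: float | None = None) -> tuple[TimeSeriesSignal, np.ndarray]:
    """Render an ECG from beat times; returns (signal, truth beat times)."""
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size == 0:
        raise ValueError("no beat times given")
    if fs < 128:
        raise ValueError(f"fs must be >= 128 Hz, got {fs}")
    if beat_times.size > 1 and np.min(np.diff(beat_times)) < 0.2:
        raise ValueError("beats closer than 200 ms cannot be rendered")
    if duration is None:
        duration = float(beat_times[-1]) + 0.6
    n = int(round(duration * fs))
    samples = np.zeros(n)
    t = np.arange(n) / fs
    for off, amp, width in _ECG_WAVES:
        centers = beat_times + off
        # render each wave over +/-4 sigma only
        for c in centers:
            i0 = max(0, int((c - 4 * width) * fs))
            i1 = min(n, int((c + 4 * width) * fs) + 1)
            if i1 > i0:
                samples[i0:i1] += amp * np.exp(
                    -0.5 * ((t[i0:i1] - c) / width) ** 2
                )
    if noise is not None:
        if rng is None:
            rng = np.random.default_rng(0)
        samples = noise.apply(samples, fs, rng)
    return TimeSeriesSignal(samples, fs, SignalKind.ECG, units="mV"), beat_times


def synth_ppg(beat_times, fs: float = 512.0,
              noise: NoiseSpec | None = None,
              rng: np.random.Generator | None = None) -> tuple[TimeSeriesSignal, np.ndarray]:
    """Render a PPG pulse train: one smooth systolic wave per beat.

    The pulse peak is placed at the beat time (pulse-transit delay is a
    constant offset and is irrelevant to interval analysis), modelled as
    a single wide Gaussian upstroke per beat.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size == 0:
        raise ValueError("no beat times given")
    duration = float(beat_times[-1]) + 0.8
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    samples = np.zeros(n)
    width = 0.12
    for c in beat_times:
        i0 = max(0, int((c - 4 * width) * fs))
        i1 = min(n, int((c + 4 * width) * fs) + 1)
        samples[i0:i1] += np.exp(-0.5 * ((t[i0:i1] - c) / width) ** 2)
    if noise is not None:
        if rng is None:
            rng = np.random.default_rng(0)
        samples = noise.apply(samples, fs, rng)
    return TimeSeriesSignal(samples, fs, SignalKind.PPG), beat_times


def synth_resp(rate: float, insp_frac: float = 0.4, fs: float = 64.0,
               duration: float = 300.0,
               noise: NoiseSpec | None = None,
               rng: np.random.Generator | None = None
               ) -> tuple[TimeSeriesSignal, RespCycleSeries]:
    """Respiration waveform with known breath segmentation.

    Each cycle rises (inspiration) over ``insp_frac`` of the period with
    a raised-cosine profile and falls (expiration) over the remainder.
    Truth troughs sit at cycle starts and peaks at the end of
    inspiration; only complete cycles are annotated.
    """
    if not 2 <= rate <= 30:
        raise ValueError(f"breathing rate {rate} b/min outside [2, 30]")
    if not 0.1 < insp_frac < 0.9:
        raise ValueError(f"insp_frac {insp_frac} outside (0.1, 0.9)")
    period = 60.0 / rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phase = (t % period) / period
    samples = np.where(
        phase < insp_frac,
        0.5 - 0.5 * np.cos(np.pi * phase / insp_frac),
        0.5 + 0.5 * np.cos(np.pi * (phase - insp_frac) / (1 - insp_frac)),
    )
    if noise is not None:
        if rng is None:
            rng = np.random.default_rng(0)
        samples = noise.apply(samples, fs, rng)
    n_complete = int(duration // period)
    troughs = np.arange(n_complete + 1) * period
    troughs = troughs[troughs <= duration]
    peaks = troughs[:-1] + insp_frac * period
    truth = RespCycleSeries(troughs, peaks)
    return TimeSeriesSignal(samples, fs, SignalKind.RESP), truth


@dataclass(frozen=True)
class GroupProfile:
    """Generator regime for one study-like group.

    ``sdnn_target`` decomposes into RSA modulation at ``breathing_rate``
    plus band-limited noise; a sinusoidal peak-to-trough oscillation g
    contributes g/(2*sqrt(2)) ms of SD.
    """

    mean_rr: float
    breathing_rate: float   # b/min at rest
    rsa_gain: float         # ms peak-to-trough at the group's breathing rate
    rr_noise_sd: float      # ms
    resonance_freq: float = 6.0


# Regimes chosen so the analysis pipeline recovers group mean SDNN near
# (56, 28, 55) ms and a stressed (high LF/HF) pre-training group:
# the pre-training group breathes fast (HF band) with little slow
# variability, the baseline and post-training groups carry substantial
# slow (LF-band) oscillation.
DEFAULT_GROUP_PROFILES = {
    "BL": GroupProfile(mean_rr=850.0, breathing_rate=12.2, rsa_gain=110.0,
                       rr_noise_sd=46.6),
    "PRE_RFT": GroupProfile(mean_rr=780.0, breathing_rate=19.3, rsa_gain=35.0,
                            rr_noise_sd=29.1),
    "POST_RFT": GroupProfile(mean_rr=850.0, breathing_rate=13.5, rsa_gain=105.0,
                             rr_noise_sd=47.0),
}


def make_cohort(n_per_group: int, group_profiles: dict | None = None,
                seed: int = 0, duration: float = 300.0) -> dict:
    """Generate a three-group synthetic study dataset.

    Returns ``{label: [subject, ...]}`` where each subject is a dict
    with the interval series, beat times, respiration truth and the
    generating profile.  Deterministic under ``seed``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if group_profiles is None:
        group_profiles = DEFAULT_GROUP_PROFILES
    root = np.random.SeedSequence(seed)
    cohort: dict[str, list] = {}
    for label, profile in group_profiles.items():
        cohort[label] = []
        for child in root.spawn(n_per_group):
            rng = np.random.default_rng(child)
            jitter = 1.0 + rng.normal(0.0, 0.03)
            model = RSAModel(
                mean_rr=profile.mean_rr * jitter,
                resonance_freq=profile.resonance_freq,
                peak_gain=profile.rsa_gain,
                gain_width=50.0,  # flat curve: rsa_gain applies at the rest rate
                rr_noise_sd=profile.rr_noise_sd,
            )
            rr, beats = synth_rr(model, profile.breathing_rate, duration, rng=rng)
            resp, resp_truth = synth_resp(
                profile.breathing_rate, insp_frac=0.4, duration=duration
            )
            cohort[label].append(
                {
                    "rr": rr,
                    "beat_times": beats,
                    "resp": resp,
                    "resp_truth": resp_truth,
                    "profile": profile,
                }
            )
    return cohort
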