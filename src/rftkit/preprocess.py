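"""Digital cleaning chain for raw cardiorespiratory channels.

The chain mirrors a wearable monitor's software front end: a 60 Hz notch
against powerline pickup, a linear-phase FIR band-pass against baseline
wander, a two-stage multi-scale morphological (3M) filter against
impulsive electrode/motion artifacts and residual drift, and a
smoothing/normalization step (DOM) that maps each epoch onto [0, 1].

All filters are zero-phase: the IIR notch is applied forward-backward,
and the FIR stages are linear-phase kernels applied once with their
group delay compensated, using reflection padding at the edges.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal as sps

from .signal_core import SignalKind, TimeSeriesSignal

__all__ = [
    "notch_60",
    "bandpass_fir",
    "morph_filter_3m",
    "dom_smooth",
    "default_bandpass",
    "default_se_scales",
    "preprocess_signal",
]

#: default band-pass edges per channel kind, Hz
DEFAULT_BANDS = {
    SignalKind.ECG: (0.5, 40.0),
    SignalKind.PPG: (0.1, 20.0),
    SignalKind.RESP: (0.1, 10.0),
}


def default_bandpass(kind: SignalKind) -> tuple[float, float]:
    return DEFAULT_BANDS[kind]


def _odd(n: int) -> int:
    n = max(1, int(round(n)))
    return n if n % 2 == 1 else n + 1


def default_se_scales(fs: float) -> tuple[int, int, int]:
    """Flat structuring-element lengths (samples) for the 3M filter.

    A flat opening preserves a peak only down to its value half an SE
    away from the apex, so B1 must be far shorter than the QRS rise time
    to keep R-wave attenuation below ~10%: 10 ms covers spike and
    contact artifacts while leaving beat morphology in place.  B2/B3 are
    longer than a QRS but shorter than a beat, so the opening/closing
    pair tracks the baseline through the complexes.
    """
    return _odd(0.01 * fs), _odd(0.2 * fs), _odd(0.3 * fs)


def notch_60(sig: TimeSeriesSignal, freq: float = 60.0, q: float = 30.0) -> TimeSeriesSignal:
    """Zero-phase second-order IIR notch at the powerline frequency."""
    if sig.fs <= 2 * freq:
        raise ValueError(
            f"notch at {freq} Hz needs fs > {2 * freq} Hz, got {sig.fs}"
        )
    b, a = sps.iirnotch(freq, q, fs=sig.fs)
    return sig.replace_samples(sps.filtfilt(b, a, sig.samples))


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply an odd-length linear-phase FIR with zero net delay.

    Reflection padding by half the kernel on each side, FFT convolution,
    then the central segment — equivalent to filtfilt for a symmetric
    kernel but a single pass, so the magnitude response is not squared.
    """
    m = len(taps) // 2
    if len(x) <= m:
        raise ValueError(f"signal ({len(x)} samples) shorter than filter delay {m}")
    padded = np.pad(x, m, mode="reflect")
    y = sps.fftconvolve(padded, taps, mode="same")
    return y[m:-m]


def bandpass_fir(sig: TimeSeriesSignal, lo: float | None = None,
                 hi: float | None = None, transition: float = 0.5) -> TimeSeriesSignal:
    """Linear-phase FIR band-pass; defaults per channel kind.

    The signal mean is removed before filtering so the DC component is
    eliminated exactly rather than only by the stopband attenuation.
    ``transition`` sets the design transition width at the low edge, Hz.
    """
    if lo is None or hi is None:
        d_lo, d_hi = default_bandpass(sig.kind)
        lo = d_lo if lo is None else lo
        hi = d_hi if hi is None else hi
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got ({lo}, {hi})")
    if hi >= sig.fs / 2:
        raise ValueError(f"high edge {hi} Hz >= Nyquist ({sig.fs / 2} Hz)")
    numtaps = _odd(3.3 * sig.fs / transition)
    numtaps = min(numtaps, _odd(len(sig.samples) - 2))
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=sig.fs)
    x = sig.samples - sig.samples.mean()
    return sig.replace_samples(_zero_phase_fir(x, taps))


def _open(x, size):
    return ndimage.grey_opening(x, size=size, mode="reflect")


def _close(x, size):
    return ndimage.grey_closing(x, size=size, mode="reflect")


def morph_filter_3m(sig: TimeSeriesSignal,
                    se_scales: tuple[int, int, int] | None = None,
                    return_stages: bool = False):
    """Two-stage multi-scale morphological filter with flat structuring elements.

    Stage 1 (impulse suppression, scale B1)::

        y1 = 0.5 * (close(open(x, B1), B1) + open(close(x, B1), B1))

    the open-close/close-open average removes positive and negative
    impulses narrower than B1 symmetrically.

    Stage 2 (baseline correction, scales B2 and B3)::

        baseline = close(open(y1, B2), B3);   y = y1 - baseline

    an opening longer than the QRS flattens the complexes, the closing
    fills the residual troughs, and the difference removes drift while
    leaving beat morphology in place.  Output length equals input length
    (reflection padding at the edges).

    With ``return_stages=True`` returns ``(y, y1, baseline)``.
    """
    if se_scales is None:
        se_scales = default_se_scales(sig.fs)
    b1, b2, b3 = (int(s) for s in se_scales)
    for s in (b1, b2, b3):
        if s < 1 or s % 2 == 0:
            raise ValueError(f"structuring element lengths must be odd and >= 1, got {se_scales}")
        if s >= len(sig.samples):
            raise ValueError(
                f"structuring element ({s} samples) not shorter than signal "
                f"({len(sig.samples)} samples)"
            )
    x = sig.samples
    y1 = 0.5 * (_close(_open(x, b1), b1) + _open(_close(x, b1), b1))
    baseline = _close(_open(y1, b2), b3)
    y = y1 - baseline
    out = sig.replace_samples(y)
    if return_stages:
        return out, sig.replace_samples(y1), sig.replace_samples(baseline)
    return out


def dom_smooth(sig: TimeSeriesSignal, window: int = 9) -> TimeSeriesSignal:
    """Moving-average smoothing followed by per-epoch min-max normalization.

    The window must be odd so the average is centred (zero phase).  The
    output lies in [0, 1]; a constant input, having no range, maps to an
    all-0.5 signal by convention.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window >= len(sig.samples):
        raise ValueError(f"window {window} >= signal length {len(sig.samples)}")
    kernel = np.full(window, 1.0 / window)
    smoothed = _zero_phase_fir(sig.samples, kernel)
    lo, hi = smoothed.min(), smoothed.max()
    if hi - lo < 1e-12 * max(1.0, abs(hi)):
        return sig.replace_samples(np.full_like(smoothed, 0.5))
    return sig.replace_samples((smoothed - lo) / (hi - lo))


def preprocess_signal(sig: TimeSeriesSignal, use_3m: bool = True,
                      notch: bool = True) -> TimeSeriesSignal:
    """The standard cleaning chain for one channel: notch, band-pass, 3M."""
    out = sig
    if notch and sig.fs > 120:
        out = notch_60(out)
    out = bandpass_fir(out)
    if use_3m and sig.kind is not SignalKind.RESP:
        out = morph_filter_3m(out)
    return out
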