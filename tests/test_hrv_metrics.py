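"""HRV metric arithmetic, spectral estimation and coherence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rftkit.detectors import RespCycleSeries
from rftkit.hrv_metrics import (
    Spectrum,
    band_powers,
    coherence_ratio,
    compute_hrv_metrics,
    normalized_units,
    resp_stats,
    rmssd,
    rr_psd,
    sdnn,
)
from rftkit.signal_core import IntervalKind, IntervalSeries
from rftkit.synth_signals import RSAModel, synth_rr


def _series(iv):
    return IntervalSeries(np.asarray(iv, dtype=float), IntervalKind.RR)


def _modulated(freq_hz, duration=300.0, mean=800.0, amp_ms=50.0):
    """RR tachogram sinusoidally modulated at freq_hz, beat-sampled."""
    model = RSAModel(mean_rr=mean, resonance_freq=60.0 * freq_hz,
                     peak_gain=2 * amp_ms, gain_width=1e6, rr_noise_sd=0.0)
    return synth_rr(model, 60.0 * freq_hz, duration)


class TestTimeDomain:
    def test_sdnn_constant_is_zero(self):
        assert sdnn(_series([800.0] * 4)) == 0.0

    def test_sdnn_hand_value(self):
        assert sdnn(_series([790.0, 810.0])) == pytest.approx(14.142, abs=1e-3)

    def test_sdnn_matches_brute_force(self, rng):
        iv = rng.normal(800, 50, 100)
        brute = np.sqrt(np.sum((iv - iv.mean()) ** 2) / (len(iv) - 1))
        assert sdnn(iv) == pytest.approx(brute, abs=1e-9)

    def test_sdnn_recovers_generator_sd(self):
        rng = np.random.default_rng(7)
        iv = rng.normal(800.0, 50.0, 5000)
        assert 48.0 <= sdnn(iv) <= 52.0

    def test_rmssd_hand_values(self):
        assert rmssd(_series([800.0, 800.0, 800.0])) == 0.0
        assert rmssd(_series([800.0, 810.0, 790.0])) == pytest.approx(15.811, abs=1e-3)

    def test_rmssd_alternation_exact(self):
        iv = np.tile([790.0, 810.0], 50)
        assert rmssd(_series(iv)) == pytest.approx(20.0, abs=1e-9)

    def test_rmssd_matches_brute_force(self, rng):
        iv = rng.normal(800, 30, 200)
        brute = np.sqrt(np.mean([(iv[i + 1] - iv[i]) ** 2 for i in range(len(iv) - 1)]))
        assert rmssd(iv) == pytest.approx(brute, abs=1e-9)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            sdnn(_series([800.0]))
        with pytest.raises(ValueError):
            rmssd(_series([800.0, 810.0]))


class TestSpectrum:
    def test_peak_at_modulation_frequency_lf(self):
        rr, _ = _modulated(0.10)
        spec = rr_psd(rr)
        f_peak = spec.freqs[np.argmax(spec.power)]
        assert f_peak == pytest.approx(0.10, abs=0.01)

    def test_peak_in_hf_band(self):
        rr, _ = _modulated(0.25)
        spec = rr_psd(rr)
        f_peak = spec.freqs[np.argmax(spec.power)]
        assert 0.15 <= f_peak <= 0.4

    def test_constant_rr_negligible_power(self):
        model = RSAModel(peak_gain=0.0, rr_noise_sd=0.0)
        rr, _ = synth_rr(model, 6.0, 300.0)
        tp, _, _ = band_powers(rr_psd(rr))
        assert tp < 1.0

    def test_short_record_rejected(self):
        model = RSAModel(peak_gain=0.0)
        rr, _ = synth_rr(model, 6.0, 90.0)
        with pytest.raises(ValueError):
            rr_psd(rr)

    def test_parseval_total_power_close_to_variance(self):
        rr, beats = _modulated(0.10, duration=600.0)
        spec = rr_psd(rr)
        tp, _, _ = band_powers(spec)
        grid = np.arange(beats[1], beats[-1], 0.25)
        var = np.var(np.interp(grid, beats[1:], rr.intervals))
        assert tp == pytest.approx(var, rel=0.10)


class TestBandPowers:
    def test_lf_peak_concentration(self):
        rr, _ = _modulated(0.10)
        tp, lf, hf = band_powers(rr_psd(rr))
        assert lf / tp >= 0.9

    def test_zero_spectrum(self):
        f = np.arange(0, 0.51, 0.005)
        tp, lf, hf = band_powers(Spectrum(f, np.zeros_like(f)))
        assert (tp, lf, hf) == (0.0, 0.0, 0.0)

    def test_white_spectrum_band_width_ratio(self):
        f = np.arange(0, 0.51, 0.005)
        tp, lf, hf = band_powers(Spectrum(f, np.ones_like(f)))
        assert lf == pytest.approx(0.11, abs=1e-9)
        assert hf == pytest.approx(0.25, abs=1e-9)
        assert lf / hf == pytest.approx(0.44, abs=1e-9)

    def test_coarse_grid_rejected(self):
        f = np.arange(0, 0.5, 0.02)
        with pytest.raises(ValueError):
            band_powers(Spectrum(f, np.ones_like(f)))

    def test_tp_bounds_band_sum(self):
        rr, _ = _modulated(0.12, duration=300.0)
        tp, lf, hf = band_powers(rr_psd(rr))
        assert tp >= lf + hf - 1e-9


class TestNormalizedUnits:
    def test_formula(self):
        lf_nu, hf_nu, ratio = normalized_units(2.0, 1.0)
        assert lf_nu == pytest.approx(66.667, abs=1e-3)
        assert hf_nu == pytest.approx(33.333, abs=1e-3)
        assert ratio == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "lf,hf,expected",
        [(68.7, 31.3, 2.19), (86.5, 13.5, 6.41), (65.7, 34.3, 1.92)],
    )
    def test_published_group_means_consistent(self, lf, hf, expected):
        """Printed normalized LF/HF pairs reproduce each printed ratio."""
        lf_nu, hf_nu, ratio = normalized_units(lf, hf)
        assert lf_nu + hf_nu == pytest.approx(100.0, abs=1e-6)
        assert ratio == pytest.approx(expected, abs=0.01)

    def test_hf_zero_flags_infinity(self):
        lf_nu, hf_nu, ratio = normalized_units(1.0, 0.0)
        assert lf_nu == 100.0 and np.isinf(ratio)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            normalized_units(0.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(lf=st.floats(1e-3, 1e4), hf=st.floats(1e-3, 1e4))
    def test_sum_always_100_and_ratio_consistent(self, lf, hf):
        lf_nu, hf_nu, ratio = normalized_units(lf, hf)
        assert lf_nu + hf_nu == pytest.approx(100.0, abs=1e-6)
        assert ratio == pytest.approx(lf_nu / hf_nu, rel=1e-6)


class TestCoherenceRatio:
    def test_resonant_modulation_is_coherent(self):
        rr, _ = _modulated(0.10, duration=300.0)
        assert coherence_ratio(rr_psd(rr)) >= 2.0

    def test_white_intervals_incoherent(self):
        rng = np.random.default_rng(3)
        iv = rng.normal(800.0, 40.0, 800)
        t = np.cumsum(iv) / 1000.0
        spec = rr_psd(IntervalSeries(np.clip(iv, 201, 2999), IntervalKind.RR), t)
        assert coherence_ratio(spec) < 0.5

    def test_zero_power_rejected(self):
        f = np.arange(0, 0.51, 0.005)
        with pytest.raises(ValueError):
            coherence_ratio(Spectrum(f, np.zeros_like(f)))


class TestRespStats:
    def test_uniform_cycles(self):
        troughs = np.arange(13) * 5.0
        peaks = troughs[:-1] + 2.5
        st_ = resp_stats(RespCycleSeries(troughs, peaks))
        assert st_.breathing_rate == pytest.approx(12.0)
        assert st_.breathing_rate == pytest.approx(
            60.0 / np.mean(np.diff(troughs)), abs=1e-6
        )

    def test_paced_resonance_rate(self):
        troughs = np.arange(31) * 10.0
        peaks = troughs[:-1] + 4.0
        assert resp_stats(RespCycleSeries(troughs, peaks)).breathing_rate == pytest.approx(6.0)

    def test_generator_truth_recovered(self):
        from rftkit.detectors import detect_resp_cycles
        from rftkit.synth_signals import synth_resp

        resp, _ = synth_resp(12.0, insp_frac=0.3, duration=300.0)
        st_ = resp_stats(detect_resp_cycles(resp))
        assert st_.breathing_rate == pytest.approx(12.0, abs=0.2)
        assert st_.mean_insp == pytest.approx(1.5, abs=0.1)
        assert st_.mean_exp == pytest.approx(3.5, abs=0.1)


def test_slowing_modulation_raises_lf_share():
    """Moving RSA from HF (0.25 Hz) to LF (0.1 Hz) raises lf_nu and lf_hf."""
    rr_fast, _ = _modulated(0.25)
    rr_slow, _ = _modulated(0.10)
    m_fast = compute_hrv_metrics(rr_fast)
    m_slow = compute_hrv_metrics(rr_slow)
    assert m_slow.lf_nu > m_fast.lf_nu
    assert m_slow.lf_hf > m_fast.lf_hf
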