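import numpy as np
import pytest

from rftkit.synth_signals import RSAModel, synth_ecg, synth_rr


@pytest.fixture(scope="session")
def steady_beats():
    """Noise-free 70 bpm beat train, 60 s."""
    model = RSAModel(mean_rr=857.0, peak_gain=0.0, rr_noise_sd=0.0)
    _, beats = synth_rr(model, 6.0, 60.0)
    return beats


@pytest.fixture(scope="session")
def clean_ecg(steady_beats):
    """Rendered noise-free ECG at 512 Hz plus truth beat times."""
    sig, truth = synth_ecg(steady_beats, fs=512.0)
    return sig, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
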