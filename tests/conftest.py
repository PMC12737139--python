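import numpy as np
import pytest

from aldtf import SampledSignal, synth_noisy_ecg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_signal(rng):
    return SampledSignal(rng.standard_normal(512), fs=256.0, label="random")


@pytest.fixture
def noisy_ecg_pair():
    """Synthetic ECG + white noise at 5 dB input SNR, seed 42."""
    return synth_noisy_ecg("WHITE", 5.0, fs=360.0, duration_s=10.0, heart_rate_bpm=72.0, seed=42)
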