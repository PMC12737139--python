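"""Seeded generators: ECG morphology, noise taxonomy, exact SNR mixing."""

import numpy as np
import pytest
from scipy.signal import find_peaks, periodogram

from aldtf import (
    mix_at_snr,
    signal_nzopp,
    snr,
    synth_ecg,
    synth_fiber_cardioresp,
    synth_noise,
    synth_noisy_ecg,
)
from aldtf.exceptions import DegenerateSignalError, DomainError, LengthMismatchError


def band_power_fraction(sig, f_lo, f_hi):
    f, p = periodogram(sig.samples, sig.fs)
    band = (f >= f_lo) & (f <= f_hi)
    return p[band].sum() / p.sum()


def test_ecg_r_peak_count_and_spacing():
    sig = synth_ecg(360.0, 10.0, 60.0, rr_jitter_frac=0.0, seed=5)
    peaks, _ = find_peaks(sig.samples, height=0.8)
    assert len(peaks) == 10
    assert np.all(np.diff(peaks) == 360)
    assert np.abs(sig.samples).max() == pytest.approx(1.0)


def test_ecg_determinism_and_period_detection():
    a = synth_ecg(seed=9)
    b = synth_ecg(seed=9)
    assert np.array_equal(a.samples, b.samples)
    hr = 75.0
    sig = synth_ecg(360.0, 10.0, hr, rr_jitter_frac=0.0, seed=1)
    res = signal_nzopp(sig)
    assert abs(res.peak_lag - 360.0 * 60.0 / hr) <= 2


def test_ecg_parameter_validation():
    with pytest.raises(DomainError):
        synth_ecg(fs=50.0)
    with pytest.raises(DomainError):
        synth_ecg(heart_rate_bpm=300.0)
    with pytest.raises(DomainError):
        synth_ecg(rr_jitter_frac=0.5)


@pytest.mark.parametrize("kind", ["BW", "EM", "MA", "MIX", "WHITE"])
def test_noise_normalization_and_determinism(kind):
    a = synth_noise(kind, 360.0, 3600, seed=11)
    b = synth_noise(kind, 360.0, 3600, seed=11)
    assert np.array_equal(a.samples, b.samples)
    assert abs(a.samples.mean()) < 1e-6
    assert a.power() == pytest.approx(1.0, abs=1e-6)


def test_noise_spectral_contracts():
    bw = synth_noise("BW", 360.0, 7200, seed=2)
    assert band_power_fraction(bw, 0.0, 1.0) > 0.90
    ma = synth_noise("MA", 360.0, 7200, seed=2)
    assert band_power_fraction(ma, 15.0, 110.0) > 0.95
    with pytest.raises(DomainError):
        synth_noise("PINK", 360.0, 100)


@pytest.mark.parametrize("target", [-10.0, 0.0, 5.0, 20.0])
def test_mix_at_snr_exact(target):
    clean = synth_ecg(seed=3)
    noise = synth_noise("WHITE", clean.fs, len(clean), seed=4)
    pair = mix_at_snr(clean, noise, target)
    assert snr(pair.clean, pair.noisy) == pytest.approx(target, abs=1e-9)
    # the pair decomposes exactly: noisy - clean == scaled noise
    assert np.array_equal(pair.noisy.samples - pair.clean.samples, pair.noise.samples)
    if target == -10.0:
        assert pair.noise.power() == pytest.approx(10.0 * clean.power(), rel=1e-9)


def test_mix_errors():
    clean = synth_ecg(seed=3)
    with pytest.raises(LengthMismatchError):
        mix_at_snr(clean, synth_noise("WHITE", clean.fs, 100, 1), 5.0)
    flat = clean.with_samples(np.zeros(len(clean)) + 0.0)
    with pytest.raises(DegenerateSignalError):
        mix_at_snr(flat, synth_noise("WHITE", clean.fs, len(clean), 1), 5.0)


def test_synth_noisy_ecg_round_trip():
    pair = synth_noisy_ecg("MIX", 5.0, seed=8)
    assert pair.noise_kind == "MIX"
    assert snr(pair.clean, pair.noisy) == pytest.approx(5.0, abs=1e-9)
    again = synth_noisy_ecg("MIX", 5.0, seed=8)
    assert np.array_equal(pair.noisy.samples, again.noisy.samples)


def test_fiber_cardioresp_spectrum_and_periods():
    sig = synth_fiber_cardioresp(512.0, 20.0, heart_rate_bpm=70.0, resp_rate_bpm=15.0, seed=6)
    f, p = periodogram(sig.samples, sig.fs)
    assert f[np.argmax(p)] == pytest.approx(0.25, abs=0.05)  # dominant line at 15 bpm
    assert np.array_equal(
        sig.samples, synth_fiber_cardioresp(512.0, 20.0, 70.0, 15.0, seed=6).samples
    )
    # the respiratory autocorrelation lobe dominates every admissible lag
    # window, so recover the cardiac period from the detail bands only
    # (wavelet high-pass: zero the 0-2 Hz approximation at depth 7)
    from aldtf import decompose, reconstruct

    dec = decompose(sig, levels=7)
    import dataclasses

    cardiac = reconstruct(
        dataclasses.replace(dec, approximation=np.zeros_like(dec.approximation))
    )
    res = signal_nzopp(cardiac, min_period_s=0.4, max_period_s=1.5)
    assert abs(res.peak_lag - 512.0 * 60.0 / 70.0) <= 0.05 * 512.0
    with pytest.raises(DomainError):
        synth_fiber_cardioresp(resp_rate_bpm=100.0, heart_rate_bpm=70.0)
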