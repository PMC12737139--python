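"""Reference-based quality metrics and their algebraic identities."""

import math

import numpy as np
import pytest

from aldtf import SampledSignal, delta_metrics, prd, rmse, sinad, snr
from aldtf.exceptions import DegenerateSignalError, LengthMismatchError


def sig(values, fs=4.0):
    return SampledSignal(np.array(values, dtype=float), fs)


X = sig([1.0, 1.0, 1.0, 1.0])
YIN = sig([1.0, 1.0, 1.0, -1.0])
YOUT = sig([1.0, 1.0, 1.0, 0.0])


def test_hand_computed_examples():
    assert snr(X, YOUT) == pytest.approx(10 * math.log10(4), abs=1e-4)  # 6.0206 dB
    assert rmse(X, YOUT) == pytest.approx(0.5)
    assert prd(X, YOUT) == pytest.approx(50.0)
    assert sinad(X, YIN, YOUT) == pytest.approx(10 * math.log10(2), abs=1e-4)  # 3.0103 dB


def test_perfect_estimate_sentinels():
    assert snr(X, X) == math.inf
    assert rmse(X, X) == 0.0
    assert prd(X, X) == 0.0
    rep = delta_metrics(X, YIN, X)
    assert rep.delta_snr_db == math.inf
    assert rep.pn == 0.0


def test_zero_estimate_gives_zero_db():
    z = sig([0.0, 0.0, 0.0, 0.0])
    assert snr(X, z) == pytest.approx(0.0)


def test_scale_behaviour(rng):
    x = SampledSignal(rng.standard_normal(100), 10.0)
    y = SampledSignal(x.samples + rng.standard_normal(100) * 0.1, 10.0)
    c = 3.7
    xs, ys = x.with_samples(c * x.samples), y.with_samples(c * y.samples)
    assert rmse(xs, ys) == pytest.approx(c * rmse(x, y))
    assert prd(xs, ys) == pytest.approx(prd(x, y))
    yin = SampledSignal(x.samples + rng.standard_normal(100) * 0.3, 10.0)
    assert sinad(xs, yin.with_samples(c * yin.samples), ys) == pytest.approx(sinad(x, yin, y))


def test_snr_prd_identity(rng):
    """snr = -20 log10(prd/100), the identity linking the two definitions."""
    for _ in range(10):
        x = SampledSignal(rng.standard_normal(256), 100.0)
        y = SampledSignal(x.samples + 0.3 * rng.standard_normal(256), 100.0)
        assert snr(x, y) == pytest.approx(-20 * math.log10(prd(x, y) / 100), abs=1e-9)


def test_permutation_covariance(rng):
    x = SampledSignal(rng.standard_normal(128), 50.0)
    yin = SampledSignal(x.samples + rng.standard_normal(128), 50.0)
    yout = SampledSignal(x.samples + 0.2 * rng.standard_normal(128), 50.0)
    perm = rng.permutation(128)
    rep = delta_metrics(x, yin, yout)
    rep_p = delta_metrics(
        x.with_samples(x.samples[perm]),
        yin.with_samples(yin.samples[perm]),
        yout.with_samples(yout.samples[perm]),
    )
    for f in ("snr_db", "sinad_db", "rmse", "prd_percent", "delta_snr_db", "delta_sinad_db"):
        assert getattr(rep, f) == pytest.approx(getattr(rep_p, f))


def test_delta_conventions(rng):
    x = SampledSignal(rng.standard_normal(64), 10.0)
    yin = SampledSignal(x.samples + rng.standard_normal(64), 10.0)
    rep = delta_metrics(x, yin, yin)  # "denoiser" that does nothing
    assert rep.delta_snr_db == pytest.approx(0.0)
    yout = SampledSignal(x.samples + 0.1 * rng.standard_normal(64), 10.0)
    rep = delta_metrics(x, yin, yout)
    assert rep.delta_snr_db == pytest.approx(snr(x, yout) - snr(x, yin))
    assert rep.delta_sinad_db == pytest.approx(sinad(x, yin, yout) - sinad(x, yin, yin))


def test_error_paths():
    with pytest.raises(LengthMismatchError):
        snr(X, sig([1.0, 2.0]))
    with pytest.raises(DegenerateSignalError):
        snr(sig([0.0, 0.0, 0.0, 0.0]), YOUT)
    with pytest.raises(DegenerateSignalError):
        sinad(X, X, X)  # Pn + Pd = 0


def test_report_serializes_sentinels():
    rep = delta_metrics(X, YIN, X)
    d = rep.to_dict()
    assert d["delta_snr_db"] == "inf"
    assert d["rmse"] == 0.0
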