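"""NACF, NZOPP peak picking, and the five-point bracket search."""

import math

import numpy as np
import pytest

from aldtf import SampledSignal, nacf, nzopp, optimize_tuning_factor, signal_nzopp
from aldtf.exceptions import (
    DegenerateSignalError,
    DomainError,
    OptimizationError,
    SignalTooShortError,
)


def nacf_reference(y):
    """Independent brute-force evaluation of the tail-normalized autocorrelation."""
    n = len(y)
    total = sum(v * v for v in y)
    out = []
    for k in range(n):
        num = sum(y[i] * y[i + k] for i in range(n - k))
        tail = sum(y[i + k] ** 2 for i in range(n - k))
        denom = math.sqrt(total) * math.sqrt(tail)
        out.append(num / denom if denom > 0 else 0.0)
    return np.array(out)


def grid_argmax(f, lo, hi):
    """Two-stage grid-scan oracle: coarse 1e-3 sweep, then 1e-7 steps locally."""
    coarse = np.linspace(lo, hi, int((hi - lo) / 1e-3) + 2)
    i = int(np.argmax(f(coarse)))
    a = coarse[max(0, i - 1)]
    b = coarse[min(len(coarse) - 1, i + 1)]
    fine = np.arange(a, b, 1e-7)
    return float(fine[np.argmax(f(fine))])


@pytest.mark.parametrize(
    "y, k, expected",
    [
        ([1.0, 1.0, 1.0, 1.0], 2, math.sqrt(2) / 2),
        ([1.0, -1.0, 1.0, -1.0], 1, -math.sqrt(3) / 2),
    ],
)
def test_nacf_hand_values(y, k, expected):
    prof = nacf(SampledSignal(np.array(y), 4.0))
    assert prof.values[k] == pytest.approx(expected, abs=1e-12)
    assert prof.values[0] == 1.0


def test_nacf_fft_matches_direct(rng):
    for _ in range(10):
        y = SampledSignal(rng.standard_normal(257), 100.0)
        a = nacf(y, method="fft").values
        b = nacf(y, method="direct").values
        assert np.max(np.abs(a - b)) < 1e-10
        assert np.max(np.abs(a - nacf_reference(y.samples))) < 1e-10


def test_nacf_bounded_and_scale_invariant(rng):
    y = rng.standard_normal(400)
    a = nacf(SampledSignal(y, 100.0)).values
    assert np.all(np.abs(a) <= 1.0)
    b = nacf(SampledSignal(7.3 * y, 100.0)).values
    assert np.allclose(a, b, atol=1e-12)


def test_nacf_degenerate_and_bad_method():
    with pytest.raises(DegenerateSignalError):
        nacf(SampledSignal(np.zeros(16), 10.0))
    with pytest.raises(DomainError):
        nacf(SampledSignal(np.ones(16), 10.0), method="banana")


def test_nzopp_finds_sinusoid_period():
    # 10 Hz tone: period 50 samples; k/N is small enough that the
    # tail-normalized profile's sqrt(1 - k/N) ceiling stays above 0.99
    fs, period = 500.0, 50
    t = np.arange(8192) / fs
    sig = SampledSignal(np.sin(2 * np.pi * 10.0 * t), fs)
    res = signal_nzopp(sig, min_period_s=0.08)
    assert abs(res.peak_lag - period) <= 1
    assert res.peak_value >= 0.99


def test_nzopp_low_for_white_noise():
    peaks = [
        signal_nzopp(SampledSignal(np.random.default_rng(s).standard_normal(4096), 360.0)).peak_value
        for s in range(20)
    ]
    assert max(peaks) < 0.15


def test_nzopp_pulse_train_peak_at_period_multiple():
    fs, p = 100.0, 40
    y = np.zeros(2000)
    y[::p] = 1.0
    y += 0.2  # constant offset plus period-p train
    res = signal_nzopp(SampledSignal(y, fs), min_period_s=0.25)  # excludes lags < 25
    assert res.peak_lag % p == 0


def test_nzopp_window_and_errors():
    sig = SampledSignal(np.sin(np.arange(100)), 100.0)
    with pytest.raises(SignalTooShortError):
        signal_nzopp(sig, min_period_s=0.6)
    with pytest.raises(DomainError):
        signal_nzopp(sig, min_period_s=-1.0)
    with pytest.raises(DomainError):
        signal_nzopp(sig, min_period_s=0.25, max_period_s=0.1)


def test_optimizer_quadratic():
    alpha, trace = optimize_tuning_factor(lambda a: -((a - 0.3) ** 2), 0.0, 1.0, 1e-6)
    assert abs(alpha - 0.3) < 1e-4
    assert trace.final_objective == max(
        v for it in trace.iterations for v in (it.n_start, it.n_left, it.n_mid, it.n_right, it.n_end)
    )


def test_optimizer_constant_and_monotone():
    alpha, trace = optimize_tuning_factor(lambda a: 1.0, 0.0, 1.0, 1e-6)
    last = trace.iterations[-1]
    assert last.alpha_end - last.alpha_start <= 2e-6  # final bracket below tol after contraction
    alpha, _ = optimize_tuning_factor(lambda a: a, 0.0, 1.0, 1e-6)
    assert abs(alpha - 1.0) < 1e-4


def test_optimizer_iteration_bound_and_contraction():
    lo, hi, tol = 0.0, 3.7, 1e-6
    _, trace = optimize_tuning_factor(lambda a: -abs(a - 1.234), lo, hi, tol)
    assert len(trace.iterations) <= math.ceil(math.log2((hi - lo) / tol)) + 2
    widths = [it.alpha_end - it.alpha_start for it in trace.iterations]
    assert all(b < a for a, b in zip(widths, widths[1:]))


def test_optimizer_against_grid_oracle():
    """On 50 seeded unimodal objectives the search lands within 1e-4 of the
    brute-force grid maximizer."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        m = rng.uniform(0.05, 0.95)
        p = rng.uniform(1.2, 3.0)
        c = rng.uniform(0.5, 2.0)

        def f(a, m=m, p=p, c=c):
            return -c * np.abs(a - m) ** p

        alpha, _ = optimize_tuning_factor(f, 0.0, 1.0, 1e-6)
        assert abs(alpha - grid_argmax(f, 0.0, 1.0)) <= 1e-4


def test_optimizer_errors():
    with pytest.raises(DomainError):
        optimize_tuning_factor(lambda a: a, 1.0, 0.0, 1e-6)
    with pytest.raises(DomainError):
        optimize_tuning_factor(lambda a: a, 0.0, 1.0, -1e-6)
    with pytest.raises(OptimizationError) as err:
        optimize_tuning_factor(lambda a: float("nan"), 0.0, 1.0, 1e-6)
    assert err.value.alpha is not None


def test_optimizer_caches_repeated_endpoints():
    calls = []

    def f(a):
        calls.append(a)
        return -((a - 0.5) ** 2)

    _, trace = optimize_tuning_factor(f, 0.0, 1.0, 1e-3)
    assert len(calls) == len(set(calls)) == trace.n_evaluations
    assert trace.n_evaluations < 5 * len(trace.iterations)
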