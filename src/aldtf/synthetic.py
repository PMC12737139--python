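"""Seeded generators for quasi-periodic test signals and ECG noise.

Clean signals
-------------
``synth_ecg`` builds an ECG-like waveform as a sum of per-beat Gaussian
bumps for the P, Q, R, S and T waves at fixed phase offsets and amplitudes
(R dominant), with beat onsets spaced by RR intervals carrying seeded
multiplicative jitter.  ``synth_fiber_cardioresp`` emulates a multimode
fiber cardiorespiratory trace: a dominant slow respiration sinusoid plus
smaller sharp cardiac pulses amplitude-modulated by respiration.

Noise
-----
``synth_noise`` emulates the standard ECG noise taxonomy:

* ``BW``  — baseline wander: 2-3 sinusoids below 0.5 Hz plus a slow random walk;
* ``EM``  — electrode motion: sparse step/transient artifacts convolved with a
  short exponential decay kernel;
* ``MA``  — muscle artifact: white noise band-passed to 20..min(100, 0.45 fs) Hz;
* ``MIX`` — equal-power sum of BW + EM + MA;
* ``WHITE`` — white Gaussian noise.

Every noise vector is returned zero-mean with unit mean power.
``mix_at_snr`` scales a noise vector so the noisy signal hits an exact
target input SNR.  Every generator is a pure function of its parameters and
seed: no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import butter, filtfilt

from .exceptions import DegenerateSignalError, DomainError, LengthMismatchError
from .signals import SampledSignal

__all__ = [
    "NoisySignalPair",
    "ECG_WAVES",
    "synth_ecg",
    "synth_noise",
    "mix_at_snr",
    "synth_noisy_ecg",
    "synth_fiber_cardioresp",
]

NOISE_KINDS = ("BW", "EM", "MA", "MIX", "WHITE")

# (name, offset from R peak [s], Gaussian width sigma [s], amplitude) per beat.
# Offsets and widths are fixed in absolute time, appropriate for 60-90 bpm.
ECG_WAVES: tuple[tuple[str, float, float, float], ...] = (
    ("P", -0.200, 0.040, 0.12),
    ("Q", -0.028, 0.012, -0.12),
    ("R", 0.000, 0.014, 1.00),
    ("S", 0.030, 0.012, -0.22),
    ("T", 0.240, 0.060, 0.28),
)


@dataclass(frozen=True)
class NoisySignalPair:
    """A (clean, scaled-noise, noisy) triple mixed at an exact input SNR.

    ``noisy.samples - clean.samples`` equals ``noise.samples`` exactly.
    """

    clean: SampledSignal
    noise: SampledSignal
    noisy: SampledSignal
    input_snr_db: float
    seed: Optional[int] = None
    noise_kind: str = ""


def _normalize(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-mean-power."""
    x = x - x.mean()
    p = np.sqrt(np.mean(x * x))
    if p == 0.0:
        raise DegenerateSignalError("generated noise has zero power")
    return x / p


def synth_ecg(
    fs: float = 360.0,
    duration_s: float = 10.0,
    heart_rate_bpm: float = 72.0,
    rr_jitter_frac: float = 0.03,
    seed: int = 0,
) -> SampledSignal:
    """Synthetic ECG-like signal: Gaussian P/Q/R/S/T bumps per beat, peak amplitude 1.

    Beat k's R peak sits at t_0 + sum of jittered RR intervals, with
    t_0 = RR/2 and RR_i = (60/hr) * (1 + jitter * u_i), u_i ~ U(-1, 1) from a
    seeded generator.  With zero jitter the R peaks are exactly RR apart.
    """
    if fs < 100:
        raise DomainError(f"fs must be >= 100 Hz for ECG synthesis, got {fs}")
    if not 30 <= heart_rate_bpm <= 240:
        raise DomainError(f"heart rate must be in [30, 240] bpm, got {heart_rate_bpm}")
    if not 0 <= rr_jitter_frac <= 0.2:
        raise DomainError(f"rr_jitter_frac must be in [0, 0.2], got {rr_jitter_frac}")
    if duration_s <= 0:
        raise DomainError(f"duration must be positive, got {duration_s}")
    rng = np.random.default_rng(seed)
    rr = 60.0 / heart_rate_bpm
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    y = np.zeros(n)
    # generate R-peak times covering [0, duration] with margin for edge P/T waves
    r_times = []
    tk = 0.5 * rr
    while tk < duration_s + 0.5:
        r_times.append(tk)
        tk += rr * (1.0 + rr_jitter_frac * rng.uniform(-1.0, 1.0))
    for tr in r_times:
        for _, off, width, amp in ECG_WAVES:
            center = tr + off
            lo = max(0, int(np.floor((center - 5 * width) * fs)))
            hi = min(n, int(np.ceil((center + 5 * width) * fs)) + 1)
            if hi > lo:
                y[lo:hi] += amp * np.exp(-((t[lo:hi] - center) ** 2) / (2 * width**2))
    peak = np.abs(y).max()
    if peak > 0:
        y /= peak
    return SampledSignal(
        y, fs, label=f"synth_ecg(hr={heart_rate_bpm},jitter={rr_jitter_frac},seed={seed})"
    )


def _bw(rng: np.random.Generator, fs: float, n: int) -> np.ndarray:
    t = np.arange(n) / fs
    k = int(rng.integers(2, 4))
    x = np.zeros(n)
    for _ in range(k):
        f = rng.uniform(0.05, 0.45)
        phase = rng.uniform(0, 2 * np.pi)
        x += np.sin(2 * np.pi * f * t + phase)
    walk = np.cumsum(rng.standard_normal(n))
    return _normalize(x) + 0.7 * _normalize(walk)


def _em(rng: np.random.Generator, fs: float, n: int) -> np.ndarray:
    impulses = np.zeros(n)
    mask = rng.random(n) < 1.5 / fs  # ~1.5 transient events per second
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        idx = np.array([int(rng.integers(0, n))])
    impulses[idx] = rng.standard_normal(idx.size) * rng.choice([-1.0, 1.0], idx.size)
    tau = 0.08  # decay time constant [s]
    klen = max(2, int(round(0.5 * fs)))
    kernel = np.exp(-np.arange(klen) / (tau * fs))
    return np.convolve(impulses, kernel)[:n]


def _ma(rng: np.random.Generator, fs: float, n: int) -> np.ndarray:
    lo, hi = 20.0, min(100.0, 0.45 * fs)
    if hi <= lo:
        raise DomainError(f"fs={fs} too low for muscle-artifact band [20, {hi}] Hz")
    b, a = butter(4, [lo, hi], btype="bandpass", fs=fs)
    return filtfilt(b, a, rng.standard_normal(n))


def synth_noise(kind: str, fs: float, n: int, seed: int = 0) -> SampledSignal:
    """Generate n samples of the requested noise kind, zero-mean and unit-power."""
    kind = kind.upper()
    if kind not in NOISE_KINDS:
        raise DomainError(f"unknown noise kind {kind!r}; expected one of {NOISE_KINDS}")
    if n < 2:
        raise DomainError(f"need at least 2 samples, got {n}")
    rng = np.random.default_rng(seed)
    if kind == "WHITE":
        x = rng.standard_normal(n)
    elif kind == "BW":
        x = _bw(rng, fs, n)
    elif kind == "EM":
        x = _em(rng, fs, n)
    elif kind == "MA":
        x = _ma(rng, fs, n)
    else:  # MIX: equal-power sum; one stream, drawn in fixed order
        x = (_normalize(_bw(rng, fs, n)) + _normalize(_em(rng, fs, n)) + _normalize(_ma(rng, fs, n))) / np.sqrt(3.0)
    return SampledSignal(_normalize(x), fs, label=f"synth_noise({kind},seed={seed})")


def mix_at_snr(
    clean: SampledSignal,
    noise: SampledSignal,
    target_snr_db: float,
    seed: Optional[int] = None,
    noise_kind: str = "",
) -> NoisySignalPair:
    """Scale ``noise`` so that clean + scaled noise has exactly the target SNR.

    The scale factor is c = sqrt( sum x^2 / (sum v^2 * 10^(target/10)) ).
    """
    if len(clean) != len(noise):
        raise LengthMismatchError(
            f"clean length {len(clean)} != noise length {len(noise)}"
        )
    clean.require_nonzero()
    pv = float(np.sum(noise.samples**2))
    if pv == 0.0:
        raise DegenerateSignalError("noise has zero power")
    px = float(np.sum(clean.samples**2))
    c = np.sqrt(px / (pv * 10.0 ** (target_snr_db / 10.0)))
    noisy = clean.samples + c * noise.samples
    # store the noise as the realized difference so yin - x == noise bitwise
    scaled = noisy - clean.samples
    return NoisySignalPair(
        clean=clean,
        noise=SampledSignal(scaled, clean.fs, label=noise.label + "(scaled)"),
        noisy=SampledSignal(noisy, clean.fs, label=clean.label + "+noise"),
        input_snr_db=float(target_snr_db),
        seed=seed,
        noise_kind=noise_kind or noise.label,
    )


def synth_noisy_ecg(
    noise_kind: str = "WHITE",
    input_snr_db: float = 5.0,
    fs: float = 360.0,
    duration_s: float = 10.0,
    heart_rate_bpm: float = 72.0,
    rr_jitter_frac: float = 0.03,
    seed: int = 0,
) -> NoisySignalPair:
    """One-call study condition: clean synthetic ECG plus noise at an exact SNR.

    The clean-signal and noise streams use decorrelated child seeds derived
    from ``seed``, so varying the seed varies both.
    """
    ss = np.random.SeedSequence(seed)
    s_ecg, s_noise = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    clean = synth_ecg(fs, duration_s, heart_rate_bpm, rr_jitter_frac, s_ecg)
    noise = synth_noise(noise_kind, fs, len(clean), s_noise)
    return mix_at_snr(clean, noise, input_snr_db, seed=seed, noise_kind=noise_kind.upper())


def synth_fiber_cardioresp(
    fs: float = 2048.0,
    duration_s: float = 20.0,
    heart_rate_bpm: float = 70.0,
    resp_rate_bpm: float = 15.0,
    seed: int = 0,
) -> SampledSignal:
    """Fiber-optic-like cardiorespiratory trace, peak amplitude 1.

    A dominant respiration sinusoid at resp_rate_bpm/60 Hz carries smaller,
    sharper cardiac pulses whose amplitude is modulated by the respiration
    phase; pulse timing has a small seeded jitter.
    """
    if not resp_rate_bpm < heart_rate_bpm:
        raise DomainError(
            f"respiration rate ({resp_rate_bpm}) must be below heart rate ({heart_rate_bpm})"
        )
    if resp_rate_bpm <= 0 or heart_rate_bpm > 240:
        raise DomainError("rates out of range")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    f_resp = resp_rate_bpm / 60.0
    resp = np.sin(2 * np.pi * f_resp * t)
    y = 1.0 * resp
    rr = 60.0 / heart_rate_bpm
    width = 0.030  # cardiac pulse sigma [s]
    tk = 0.5 * rr
    while tk < duration_s + 0.2:
        mod = 1.0 + 0.3 * np.sin(2 * np.pi * f_resp * tk)
        lo = max(0, int(np.floor((tk - 5 * width) * fs)))
        hi = min(n, int(np.ceil((tk + 5 * width) * fs)) + 1)
        if hi > lo:
            y[lo:hi] += 0.35 * mod * np.exp(-((t[lo:hi] - tk) ** 2) / (2 * width**2))
        tk += rr * (1.0 + 0.02 * rng.uniform(-1.0, 1.0))
    y /= np.abs(y).max()
    return SampledSignal(
        y, fs, label=f"synth_fiber(hr={heart_rate_bpm},resp={resp_rate_bpm},seed={seed})"
    )
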