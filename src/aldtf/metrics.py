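"""Reference-based signal quality metrics: SNR, RMSE, PRD, SINAD.

All metrics compare a denoised estimate ``yout`` against a clean reference
``x`` (and, for SINAD, the noisy input ``yin``):

    SNR   = 10 log10( sum x^2 / sum (yout - x)^2 )            [dB]
    RMSE  = sqrt( mean (x - yout)^2 )                         [signal units]
    PRD   = 100 sqrt( sum (x - yout)^2 / sum x^2 )            [%]
    SINAD = 10 log10( Ps / (Pn + Pd) )                        [dB]

with Ps = mean x^2, Pn = mean (yout - x)^2, Pd = mean (yout - yin)^2.
Note that Pd is the power of the *change the denoiser made*, mean
|yout - yin|^2, so SINAD penalizes both residual noise and distortion.
Improvement deltas follow the output-minus-input convention:
dSNR = SNR(x, yout) - SNR(x, yin); the input SINAD substitutes yin for yout
throughout (making its Pd term zero).

A perfect estimate has zero error power; SNR is then reported as the +inf
sentinel (serialized as the string "inf") rather than raising, so batch
reports never abort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import DegenerateSignalError, LengthMismatchError
from .signals import SampledSignal

__all__ = ["MetricsReport", "snr", "rmse", "prd", "sinad", "delta_metrics"]


@dataclass(frozen=True)
class MetricsReport:
    """Quality metrics for a (clean, noisy, denoised) signal triple."""

    snr_db: float
    sinad_db: float
    rmse: float
    prd_percent: float
    ps: float
    pn: float
    pd: float
    delta_snr_db: Optional[float] = None
    delta_sinad_db: Optional[float] = None

    def to_dict(self) -> dict:
        def san(v):
            if v is None:
                return None
            if math.isinf(v):
                return "inf" if v > 0 else "-inf"
            return v

        return {
            "snr_db": san(self.snr_db),
            "sinad_db": san(self.sinad_db),
            "rmse": self.rmse,
            "prd_percent": self.prd_percent,
            "ps": self.ps,
            "pn": self.pn,
            "pd": self.pd,
            "delta_snr_db": san(self.delta_snr_db),
            "delta_sinad_db": san(self.delta_sinad_db),
        }


def _pair(clean: SampledSignal, estimate: SampledSignal) -> tuple[np.ndarray, np.ndarray]:
    if len(clean) != len(estimate):
        raise LengthMismatchError(
            f"signal lengths differ: clean {len(clean)} vs estimate {len(estimate)}"
        )
    return clean.samples, estimate.samples


def snr(clean: SampledSignal, estimate: SampledSignal) -> float:
    """Signal-to-noise ratio in dB; +inf when the estimate is exact."""
    x, y = _pair(clean, estimate)
    clean.require_nonzero()
    err = float(np.sum((y - x) ** 2))
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(float(np.sum(x**2)) / err)


def rmse(clean: SampledSignal, estimate: SampledSignal) -> float:
    """Root mean square error, in signal units."""
    x, y = _pair(clean, estimate)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def prd(clean: SampledSignal, estimate: SampledSignal) -> float:
    """Percentage root mean square difference (0% for a perfect estimate)."""
    x, y = _pair(clean, estimate)
    clean.require_nonzero()
    return float(np.sqrt(np.sum((x - y) ** 2) / np.sum(x**2)) * 100.0)


def signal_powers(
    clean: SampledSignal, noisy: SampledSignal, denoised: SampledSignal
) -> tuple[float, float, float]:
    """(Ps, Pn, Pd): mean powers of the clean signal, the residual error of the
    denoised estimate, and the change the denoiser made to the noisy input."""
    x, yin = _pair(clean, noisy)
    _, yout = _pair(clean, denoised)
    ps = float(np.mean(np.abs(x) ** 2))
    pn = float(np.mean(np.abs(yout - x) ** 2))
    pd = float(np.mean(np.abs(yout - yin) ** 2))
    return ps, pn, pd


def sinad(clean: SampledSignal, noisy: SampledSignal, denoised: SampledSignal) -> float:
    """Signal-to-noise-and-distortion ratio in dB."""
    ps, pn, pd = signal_powers(clean, noisy, denoised)
    if pn + pd == 0.0:
        raise DegenerateSignalError("Pn + Pd is zero: denoised equals both clean and noisy")
    if ps == 0.0:
        raise DegenerateSignalError("clean signal has zero power")
    return 10.0 * math.log10(ps / (pn + pd))


def delta_metrics(
    clean: SampledSignal, noisy: SampledSignal, denoised: SampledSignal
) -> MetricsReport:
    """All base metrics for the denoised estimate plus output-minus-input deltas.

    The input-side SINAD replaces the denoised estimate with the noisy input
    throughout, so its distortion term Pd is zero and the delta isolates the
    effect of denoising.
    """
    ps, pn, pd = signal_powers(clean, noisy, denoised)
    out_snr = snr(clean, denoised)
    in_snr = snr(clean, noisy)
    out_sinad = sinad(clean, noisy, denoised)
    in_sinad = sinad(clean, noisy, noisy) if not np.array_equal(
        noisy.samples, clean.samples
    ) else math.inf
    d_snr = out_snr - in_snr
    if math.isinf(out_snr) and math.isinf(in_snr):
        d_snr = 0.0
    d_sinad = out_sinad - in_sinad
    if math.isinf(out_sinad) and math.isinf(in_sinad):
        d_sinad = 0.0
    return MetricsReport(
        snr_db=out_snr,
        sinad_db=out_sinad,
        rmse=rmse(clean, denoised),
        prd_percent=prd(clean, denoised),
        ps=ps,
        pn=pn,
        pd=pd,
        delta_snr_db=d_snr,
        delta_sinad_db=d_sinad,
    )
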