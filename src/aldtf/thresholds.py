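"""Wavelet coefficient shrinkage rules.

The adaptive layer-dependent threshold function (ALDTF) maps a wavelet
coefficient w to

    w_hat = sgn(w) * (|w| / 2) * (tanh(alpha * (|w| - lam)) + 1)

where ``lam`` is the layer threshold (coefficient-amplitude units) and
``alpha`` the layer tuning factor (inverse-amplitude units).  The bracket
``(tanh + 1) / 2`` lies in [0, 1], so the rule is a pure shrinkage:
it never increases a coefficient's magnitude.  As alpha grows the rule
approaches hard thresholding (keep coefficients above lam, zero the rest);
at the boundary |w| = lam it always returns w / 2, and at alpha = 0 it
halves every coefficient.  Classical soft and hard thresholding are provided
as baselines.

All rules act element-wise and independently on each coefficient of a layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

__all__ = [
    "CoefficientVector",
    "LayerRule",
    "apply_aldtf",
    "soft_threshold",
    "hard_threshold",
    "aldtf_shrink",
    "soft_shrink",
    "hard_shrink",
]


@dataclass(frozen=True)
class CoefficientVector:
    """Detail coefficients of one decomposition level.

    ``level`` is 1-based; level 1 is the finest (highest-frequency) band.
    """

    values: np.ndarray
    level: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(arr)):
            raise DomainError("coefficient vector contains non-finite values")
        if int(self.level) < 1:
            raise DomainError(f"decomposition level must be >= 1, got {self.level}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "level", int(self.level))

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class LayerRule:
    """Per-layer shrinkage parameters: threshold lambda_j and tuning factor alpha_j."""

    level: int
    threshold: float
    tuning: float

    def __post_init__(self) -> None:
        if int(self.level) < 1:
            raise DomainError(f"level must be >= 1, got {self.level}")
        if not (self.threshold >= 0 and np.isfinite(self.threshold)):
            raise DomainError(f"threshold must be finite and >= 0, got {self.threshold}")
        if not (self.tuning >= 0 and np.isfinite(self.tuning)):
            raise DomainError(f"tuning factor must be finite and >= 0, got {self.tuning}")
        object.__setattr__(self, "level", int(self.level))
        object.__setattr__(self, "threshold", float(self.threshold))
        object.__setattr__(self, "tuning", float(self.tuning))


def aldtf_shrink(values: np.ndarray, threshold: float, tuning: float) -> np.ndarray:
    """Element-wise ALDTF shrinkage on a raw array (fast path, no validation)."""
    w = np.asarray(values, dtype=np.float64)
    a = np.abs(w)
    return np.sign(w) * (a / 2.0) * (np.tanh(tuning * (a - threshold)) + 1.0)


def soft_shrink(values: np.ndarray, threshold: float) -> np.ndarray:
    """Element-wise soft thresholding on a raw array (fast path, no validation)."""
    w = np.asarray(values, dtype=np.float64)
    return np.sign(w) * np.maximum(np.abs(w) - threshold, 0.0)


def hard_shrink(values: np.ndarray, threshold: float) -> np.ndarray:
    """Element-wise hard thresholding on a raw array (fast path, no validation)."""
    w = np.asarray(values, dtype=np.float64)
    return np.where(np.abs(w) > threshold, w, 0.0)


def apply_aldtf(coeffs: CoefficientVector, rule: LayerRule) -> CoefficientVector:
    """Apply the adaptive layer-dependent threshold function to one layer.

    Parameters
    ----------
    coeffs
        The layer's detail coefficients.
    rule
        The layer's shrinkage rule; ``rule.level`` must match ``coeffs.level``.

    Returns
    -------
    CoefficientVector
        Shrunk coefficients, same length and level.
    """
    if rule.level != coeffs.level:
        raise DomainError(
            f"rule level {rule.level} does not match coefficient level {coeffs.level}"
        )
    return CoefficientVector(
        aldtf_shrink(coeffs.values, rule.threshold, rule.tuning), coeffs.level
    )


def _check_lambda(lam: float) -> float:
    if not (lam >= 0 and np.isfinite(lam)):
        raise DomainError(f"threshold must be finite and >= 0, got {lam}")
    return float(lam)


def soft_threshold(coeffs: CoefficientVector, lam: float) -> CoefficientVector:
    """Classical soft thresholding: sgn(w) * max(|w| - lam, 0)."""
    return CoefficientVector(soft_shrink(coeffs.values, _check_lambda(lam)), coeffs.level)


def hard_threshold(coeffs: CoefficientVector, lam: float) -> CoefficientVector:
    """Classical hard thresholding: w if |w| > lam else 0 (boundary zeroed)."""
    return CoefficientVector(hard_shrink(coeffs.values, _check_lambda(lam)), coeffs.level)
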