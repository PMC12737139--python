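"""Uniformly sampled single-channel signals.

:class:`SampledSignal` is the container every other module consumes and
produces: a real-valued sample vector plus its sampling rate.  Samples are
always stored as a contiguous float64 array; validation happens once, at
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateSignalError, DomainError

__all__ = ["SampledSignal"]


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples
        The sample values, in signal units.  Coerced to a float64 array.
    fs
        Sampling rate in Hz; must be positive.
    label
        Free-text description carried through the pipeline (e.g. the source
        file name or generator parameters).
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.ascontiguousarray(np.asarray(self.samples, dtype=np.float64))
        if arr.ndim != 1:
            raise DomainError(f"signal must be one-dimensional, got shape {arr.shape}")
        if arr.size < 2:
            raise DomainError(f"signal must have at least 2 samples, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise DomainError(f"non-finite sample at index {bad}")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise DomainError(f"sampling rate must be positive and finite, got {self.fs}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Signal duration in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, 0-based (n / fs for n = 0..N-1)."""
        return np.arange(self.samples.size) / self.fs

    def power(self) -> float:
        """Mean squared sample value."""
        return float(np.mean(self.samples**2))

    def require_nonzero(self) -> None:
        """Raise :class:`DegenerateSignalError` if the signal is identically zero."""
        if not np.any(self.samples):
            raise DegenerateSignalError("signal is identically zero")

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "SampledSignal":
        """Return a copy of this signal with new sample values (same fs)."""
        return SampledSignal(samples, self.fs, self.label if label is None else label)
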