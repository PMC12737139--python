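"""Resolved denoising configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional, Union

from .exceptions import DomainError

__all__ = ["DenoiseConfig"]


@dataclass(frozen=True)
class DenoiseConfig:
    """Parameters of the adaptive layer-dependent denoiser.

    Attributes
    ----------
    wavelet_name
        Discrete wavelet for decomposition/reconstruction.  The default
        bior6.8 biorthogonal wavelet is symmetric and near-linear-phase,
        which preserves QRS/ST morphology.
    levels
        Decomposition depth J, or ``"auto"`` to try depths 3-5 and keep the
        result with the highest periodicity score.  4 suits ECG-rate signals;
        5 suits slower fiber cardiorespiratory signals.
    threshold_method
        ``"universal"`` (default) sets each layer threshold with the robust
        median-absolute-deviation universal rule; ``"nzopp"`` instead
        maximizes the reference-free periodicity objective over
        [0, max|Dj|].  The NZOPP search tends to overshrink coarse layers
        (removing real signal energy also raises periodicity), so the
        universal rule is the sturdier default.
    min_period_s
        Shortest physiological period admitted by the periodicity objective,
        in seconds.  0.25 s admits heart rates up to 240 bpm.
    max_period_s
        Longest admissible period, in seconds (2 s admits heart rates down
        to 30 bpm).  Capping the peak-search window keeps slow out-of-band
        periodicities such as baseline wander from claiming the peak;
        ``None`` searches up to lag N/2.
    tolerance
        Bracket width at which the tuning-factor search stops.
    passes
        Number of finest-to-coarsest tuning sweeps; sweeps after the first
        stop early once the objective gain drops below 1e-4.
    alpha_arg_span
        Upper bound of each layer's tuning-factor search interval, expressed
        as the maximum value of the tanh argument at the layer's largest
        coefficient: the search covers alpha in [0, alpha_arg_span / max|Dj|].
        The span must comfortably exceed 1 so the rule can range from
        soft-like shrinkage to an effectively hard threshold.  ``None``
        selects the literal interval [0, max|Dj|] instead (only sensible
        when coefficient amplitudes are large).
    extension_mode
        Signal extension at the boundaries (symmetric half-point by default).
    seed
        Optional provenance seed echoed into reports; the pipeline itself is
        deterministic.
    """

    wavelet_name: str = "bior6.8"
    levels: Union[int, str] = 4
    threshold_method: str = "universal"
    min_period_s: float = 0.25
    max_period_s: Optional[float] = 2.0
    tolerance: float = 1e-6
    passes: int = 1
    alpha_arg_span: Optional[float] = 25.0
    extension_mode: str = "symmetric"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if isinstance(self.levels, str):
            if self.levels != "auto":
                raise DomainError(f'levels must be a positive integer or "auto", got {self.levels!r}')
        elif int(self.levels) < 1:
            raise DomainError(f"levels must be >= 1, got {self.levels}")
        if self.threshold_method not in ("nzopp", "universal"):
            raise DomainError(
                f'threshold_method must be "nzopp" or "universal", got {self.threshold_method!r}'
            )
        if not self.min_period_s > 0:
            raise DomainError(f"min_period_s must be positive, got {self.min_period_s}")
        if self.max_period_s is not None and not self.max_period_s > self.min_period_s:
            raise DomainError(
                f"max_period_s ({self.max_period_s}) must exceed min_period_s ({self.min_period_s})"
            )
        if not self.tolerance > 0:
            raise DomainError(f"tolerance must be positive, got {self.tolerance}")
        if int(self.passes) < 1:
            raise DomainError(f"passes must be >= 1, got {self.passes}")
        if self.alpha_arg_span is not None and not self.alpha_arg_span > 0:
            raise DomainError(f"alpha_arg_span must be positive, got {self.alpha_arg_span}")

    def to_dict(self) -> dict:
        return asdict(self)
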