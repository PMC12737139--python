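"""Exception hierarchy for aldtf.

All validation failures derive from :class:`AldtfError` so callers (and the
CLI) can catch one base class.  ``ValueError``/``RuntimeError`` mixins keep
the exceptions idiomatic for library users who do not import this module.
"""


class AldtfError(Exception):
    """Base class for all aldtf errors."""


class DomainError(AldtfError, ValueError):
    """A parameter is outside its admissible domain (e.g. negative threshold)."""


class DegenerateSignalError(AldtfError, ValueError):
    """The input signal is degenerate for the requested operation (e.g. all-zero)."""


class LengthMismatchError(AldtfError, ValueError):
    """Two signals that must share a length do not."""


class SignalTooShortError(AldtfError, ValueError):
    """The signal is too short for the requested lag/period analysis."""


class DepthError(AldtfError, ValueError):
    """The requested decomposition depth is infeasible for the signal length."""


class ConsistencyError(AldtfError, ValueError):
    """A decomposition's coefficients are inconsistent with its metadata."""


class OptimizationError(AldtfError, RuntimeError):
    """The tuning-factor search hit a non-finite objective value."""

    def __init__(self, message: str, alpha: float | None = None):
        super().__init__(message)
        self.alpha = alpha


class ParseError(AldtfError, ValueError):
    """An input file could not be parsed; carries a row number when known."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row
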