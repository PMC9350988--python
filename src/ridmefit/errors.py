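"""Exception hierarchy shared across the package."""


class RidmefitError(Exception):
    """Base class for all package-specific errors."""


class GridError(RidmefitError, ValueError):
    """Invalid time or distance grid (non-monotone, non-positive, NaN...)."""


class DomainError(RidmefitError, ValueError):
    """Argument outside its mathematical domain (e.g. delta not in [0, 1])."""


class DegenerateInputError(RidmefitError, ValueError):
    """Input carries no usable signal (e.g. all-zero trace)."""


class InsufficientDataError(RidmefitError, ValueError):
    """Too few points for the requested operation."""


class EstimationError(RidmefitError, RuntimeError):
    """An estimator failed to converge; carries diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class SolverError(RidmefitError, RuntimeError):
    """Regularised non-negative solver failed."""


class NumericalUnderflowError(RidmefitError, ArithmeticError):
    """Division by a vanishing background."""


class ParseError(RidmefitError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class IllConditionedFitWarning(UserWarning):
    """Isotherm fit is poorly constrained (saturated or degenerate series)."""


class ProcessingWarning(UserWarning):
    """Non-fatal irregularity during trace processing."""
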