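"""Exception types shared across the package."""


class PritdoseError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PritdoseError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(PritdoseError):
    """A value violates a domain invariant (negative uptake, bad time, ...)."""


class InsufficientDataError(PritdoseError):
    """Too few observations to perform the requested computation."""


class FitError(PritdoseError):
    """Nonlinear fit did not converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class UndefinedStatisticError(PritdoseError):
    """The requested statistic is undefined for this input (e.g. R^2 with
    zero total sum of squares but nonzero residuals, TI with zero dose)."""
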