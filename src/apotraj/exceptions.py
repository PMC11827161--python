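"""Exception hierarchy for the apotraj pipeline."""


class ApotrajError(Exception):
    """Base class for all package errors."""


class ConfigError(ApotrajError, ValueError):
    """Invalid configuration (probabilities not summing to one, n < 1, ...)."""


class DomainError(ApotrajError, ValueError):
    """Input outside the mathematical domain of an operation.

    Raised e.g. for a non-positive fractional-polynomial argument or a
    prediction grid point outside the fitted analysis window.  Never
    silently clipped.
    """


class InputError(ApotrajError, ValueError):
    """Structurally invalid input (empty pregnancy list, unknown exposure, ...)."""


class EmptyAnalysisError(ApotrajError, RuntimeError):
    """All rows were removed by the analysis filters."""


class RankDeficiencyError(ApotrajError, RuntimeError):
    """Design matrix is not of full column rank."""


class ConvergenceError(ApotrajError, RuntimeError):
    """Likelihood optimisation failed to converge."""


class BoundaryFitWarning(UserWarning):
    """A variance parameter was estimated on the boundary of its search range."""
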