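"""Exception and warning types shared across the pipeline."""


class HrmError(Exception):
    """Base class for all hrmclock errors."""


class FormatError(HrmError, ValueError):
    """A file does not have the expected table layout (missing/odd columns)."""


class ValidationError(HrmError, ValueError):
    """Parsed data violates a pipeline invariant (names the offending item)."""


class DegenerateBaselineError(ValidationError):
    """Pre- and post-melt baseline lines cross or coincide on the grid."""


class ConvergenceError(HrmError, RuntimeError):
    """An optimizer failed to converge; carries the best candidate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class ReplicateConcordanceWarning(UserWarning):
    """Duplicate reactions disagree by more than the concordance limit."""


class IllConditionedFitWarning(UserWarning):
    """A standard-curve fit is ill-conditioned (e.g. interior Df >= Dfmax)."""


class ClampWarning(UserWarning):
    """A Df value fell outside [0, Dfmax] and the methylation rate was clamped."""
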