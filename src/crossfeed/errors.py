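"""Exception types shared across the package."""


class CrossfeedError(Exception):
    """Base class for all package errors."""


class ModelFormatError(CrossfeedError):
    """A model file could not be parsed under the requested standard."""


class ModelValidationError(CrossfeedError):
    """A loaded model violates a structural invariant."""


class ConditionError(CrossfeedError):
    """A growth condition or strain specification is inconsistent."""


class SolverError(CrossfeedError):
    """The LP backend failed; carries the solver status for retries."""

    def __init__(self, message: str, status: str | None = None):
        super().__init__(message)
        self.status = status


class DomainError(CrossfeedError):
    """An operation was applied outside its domain (e.g. extinct population)."""


class UndefinedStatisticError(CrossfeedError):
    """A statistic is mathematically undefined on this input
    (e.g. assortativity with zero attribute variance)."""
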