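"""Exception hierarchy for the TURBT complexity pipeline."""


class TurbtComplexityError(Exception):
    """Base class for all package errors."""


class InvalidInputError(TurbtComplexityError, ValueError):
    """An input violates a precondition (range, shape, missing field)."""


class InsufficientDataError(InvalidInputError):
    """Too few observations to compute the requested summary."""


class DegenerateOutcomeError(InvalidInputError):
    """A binary outcome vector contains only one class."""


class SeparationError(TurbtComplexityError):
    """Complete or quasi-complete separation detected in a logistic fit."""

    def __init__(self, message: str, domain: str | None = None):
        super().__init__(message)
        self.domain = domain


class GenerationExhaustedError(TurbtComplexityError):
    """Rejection sampling could not produce a rule-consistent scenario."""


class ConfigurationError(TurbtComplexityError):
    """A pipeline configuration is inconsistent or incomplete."""
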