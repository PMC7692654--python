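"""Exception hierarchy shared across the package.

Every error raised by thermokin derives from :class:`ThermokinError`, so callers
(and the CLI) can distinguish data problems (:class:`ValidationError` and
subclasses, exit code 2) from fitting problems (:class:`FitError`, exit code 3).
"""


class ThermokinError(Exception):
    """Base class for all thermokin errors."""


class ValidationError(ThermokinError):
    """Input data violates a schema or type invariant."""


class InvalidReadingError(ValidationError):
    """A spectrophotometric reading is non-finite or implausibly large."""


class ParameterError(ValidationError):
    """A physical parameter is outside its valid domain (e.g. dry mass <= 0)."""


class EmptyInputError(ValidationError):
    """A file or record set contained no data rows (distinct from malformed)."""


class FitError(ThermokinError):
    """A regression or parameter derivation could not be carried out."""


class InsufficientDataError(FitError):
    """Too few points (or too few distinct design values) to fit."""


class DegenerateDesignError(FitError):
    """Zero variance in the predictor: the regression is undefined."""


class TransformError(FitError):
    """A value cannot be transformed (e.g. log of a non-positive concentration)."""


class NoDegradationError(FitError):
    """A thermal-resistance parameter was requested for a non-positive rate."""


class InfeasibleTargetError(ThermokinError):
    """A synthetic-data target cannot be realised under the stated constraints."""
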