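"""Exception hierarchy shared across the package."""


class AodkitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AodkitError):
    """A file does not follow the documented dialect (columns, header)."""


class RowValidationError(AodkitError):
    """A data row violates a field invariant; names the row and field."""

    def __init__(self, row: int, field: str, message: str):
        self.row = row
        self.field = field
        super().__init__(f"row {row}: field '{field}': {message}")


class SingularDesignError(AodkitError):
    """Regression design is singular (e.g. all powers identical or zero)."""


class InsufficientDataError(AodkitError):
    """Too few measurements survive the inclusion rules for a fit."""


class MissingProtocolError(AodkitError):
    """A method requires a protocol (rest, loadless, ...) the subject lacks."""


class ConfigError(AodkitError):
    """Invalid or incomplete configuration."""


class ThresholdNotReachedError(AodkitError):
    """Blood lactate never reaches the criterion concentration."""


class ZeroVarianceError(AodkitError):
    """Degenerate sample: paired differences have zero variance."""


class NonPhysicalPowerError(AodkitError):
    """A demand below the relation's intercept maps to a negative power."""
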