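"""Exception hierarchy for aptt_cwa."""


class APTTCWAError(Exception):
    """Base class for all package errors."""


class ValidationError(APTTCWAError, ValueError):
    """A domain object violates one of its invariants."""


class CalibrationError(APTTCWAError):
    """Preset calibration is infeasible or did not converge.

    Carries a ``diagnostics`` dict (targets, residuals, fitted values)
    when the optimizer ran but missed the tolerance.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoCoagulationError(APTTCWAError):
    """Curve shows no usable absorbance rise (flat / no clot)."""


class MalformedCurveError(APTTCWAError):
    """Curve rose but a required landmark (e.g. a left half-height
    crossing) could not be located."""


class SchemaError(APTTCWAError, ValueError):
    """A table read from disk is missing required columns or holds
    non-numeric values where numbers are expected."""


class IncompleteRecordError(APTTCWAError, ValueError):
    """A patient record lacks a lab value required by the operation."""


class UndefinedCorrelationError(APTTCWAError, ValueError):
    """Correlation requested on a zero-variance vector."""
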