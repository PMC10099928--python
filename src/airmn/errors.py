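"""Exception hierarchy for scoring-data validation and analysis errors."""


class AirMnError(Exception):
    """Base class for all package-specific errors."""


class InvalidRecordError(AirMnError):
    """A cell annotation or count record violates a structural invariant."""


class EmptyInputError(AirMnError):
    """An aggregation was requested over an empty collection."""


class IncompleteGroupError(AirMnError):
    """A dose group is missing data required by the requested operation."""


class InvalidTableError(AirMnError):
    """A 2x2 contingency table has negative or inconsistent counts."""


class UndefinedRelativeError(AirMnError):
    """A control-relative index is undefined because the control baseline is zero."""


class InvalidMeasurementError(AirMnError):
    """A physical reading (resistance, luminescence) is out of its valid range."""


class ConfigError(AirMnError):
    """A simulation or pipeline configuration value is invalid."""


class SchemaError(AirMnError):
    """A scoring table violates the expected schema; carries line context."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
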