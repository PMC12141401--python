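"""Exception hierarchy for cohort validation and analysis errors."""


class FrailtyFallsError(Exception):
    """Base class for all package errors."""


class SchemaError(FrailtyFallsError):
    """A row or field violates the cohort schema.

    Carries ``row`` (0-based data row, or None) and ``field`` so callers can
    report exactly where the input went wrong.
    """

    def __init__(self, message: str, *, row=None, field=None):
        self.row = row
        self.field = field
        where = []
        if row is not None:
            where.append(f"row {row}")
        if field is not None:
            where.append(f"field {field!r}")
        suffix = f" ({', '.join(where)})" if where else ""
        super().__init__(message + suffix)


class PanelMismatchError(SchemaError):
    """A laboratory result refers to an analyte absent from the active panel."""


class InclusionViolationError(SchemaError):
    """A record violates a cohort inclusion rule (e.g. age below 60)."""


class DataError(FrailtyFallsError):
    """A value is unusable for computation (non-finite, missing required item)."""


class ConfigurationError(FrailtyFallsError):
    """A simulation or study configuration is invalid or unsatisfiable."""
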