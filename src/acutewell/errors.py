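"""Exception hierarchy for the acutewell pipeline."""


class AcutewellError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AcutewellError):
    """An invalid simulation or analysis configuration (names the offending field)."""


class SchemaError(AcutewellError):
    """A cohort file violates the documented CSV schema.

    Carries enough context (file, row, field) to locate the offending value.
    """

    def __init__(self, message: str, *, file: str | None = None,
                 row: int | None = None, field: str | None = None):
        self.file = file
        self.row = row
        self.field = field
        parts = [message]
        if file is not None:
            parts.append(f"file={file}")
        if row is not None:
            parts.append(f"row={row}")
        if field is not None:
            parts.append(f"field={field}")
        super().__init__("; ".join(parts))


class AnalysisError(AcutewellError):
    """A statistical routine cannot produce a meaningful result on this input."""
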