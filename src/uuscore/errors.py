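"""Exception hierarchy shared across the package.

Validation failures carry enough context (row numbers, field names,
participant ids) for the caller to locate the offending input.
"""


class UUScoreError(Exception):
    """Base class for all package errors."""


class ConfigurationError(UUScoreError):
    """A simulation or pipeline configuration field is invalid."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class SchemaError(UUScoreError):
    """An input table is missing required columns or has wrong types."""


class ValidationError(UUScoreError):
    """A row violates a schema invariant; names the row and field."""


class InsufficientDataError(UUScoreError):
    """Too few observations for the requested computation."""


class DegenerateSplitError(UUScoreError):
    """A median split is impossible because all scores are identical."""


class MissingBaselineError(UUScoreError):
    """A participant lacks the baseline observation an imputation needs."""
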