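"""Package-wide exception types."""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class TableParseError(ValidationError):
    """A delimited/spreadsheet table could not be coerced to a feature matrix."""


class CohortConfigError(ValidationError):
    """A synthetic-cohort configuration is inconsistent."""
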