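"""Exception hierarchy.

Validation errors signal bad user input (CLI exit code 2); computation
errors signal a metric or model that cannot be produced from otherwise
valid input (CLI exit code 3).
"""


class TlsMetaError(Exception):
    """Base class for all package errors."""


class ValidationError(TlsMetaError):
    """Invalid input: bad values, inverted bounds, schema mismatch."""


class FormatError(ValidationError):
    """A file does not follow the documented CSV dialect."""


class NotComputableError(TlsMetaError):
    """A metaproperty cannot be computed from this scan (e.g. empty band)."""


class CollinearityError(TlsMetaError):
    """Rank-deficient design matrix; names the aliased columns."""

    def __init__(self, aliased_columns):
        self.aliased_columns = list(aliased_columns)
        super().__init__(
            "design matrix is rank deficient; aliased columns: "
            + ", ".join(map(str, self.aliased_columns))
        )


class ConvergenceError(TlsMetaError):
    """A model fit did not converge, or model reduction exhausted predictors."""


class StageError(TlsMetaError):
    """Failure inside a named workflow stage."""

    def __init__(self, stage, original):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
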