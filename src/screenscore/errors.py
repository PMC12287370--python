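"""Exception hierarchy shared across the package."""


class ScreenScoreError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ScreenScoreError):
    """A required column or field is missing from an input table."""


class ParseError(ScreenScoreError):
    """A cell could not be parsed; the message carries the file location."""


class ValidationError(ScreenScoreError):
    """An input violates a documented invariant (duplicate ids, empty series, ...)."""


class DegenerateControlsError(ScreenScoreError):
    """Negative-control mean does not exceed positive-control mean: the assay failed."""


class InputError(ScreenScoreError):
    """An operation received structurally unusable input (too few points, length mismatch)."""


class DomainError(ScreenScoreError):
    """A numeric argument is outside the operation's domain."""
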