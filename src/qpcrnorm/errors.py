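"""Exception hierarchy shared across the package.

All errors derive from :class:`QpcrNormError` so callers can catch one base
class; validation-style errors additionally derive from ``ValueError`` to play
well with generic input checking.
"""


class QpcrNormError(Exception):
    """Base class for all package errors."""


class SchemaError(QpcrNormError, ValueError):
    """A required column or field is missing from an input file."""


class CtParseError(QpcrNormError, ValueError):
    """A Ct cell could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class UnknownReferenceError(QpcrNormError, KeyError):
    """A group, sample or gene region was referenced that does not exist."""


class InsufficientDataError(QpcrNormError, ValueError):
    """Too few usable observations for the requested computation."""


class InvalidCurveError(QpcrNormError, ValueError):
    """A standard curve fit produced a physically impossible result."""


class ConfigurationError(QpcrNormError, ValueError):
    """Inconsistent or incomplete run configuration."""


class DomainError(QpcrNormError, ValueError):
    """An argument is outside the domain an operation is defined on."""
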