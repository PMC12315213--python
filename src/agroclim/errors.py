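"""Exception hierarchy shared across the package.

All errors raised deliberately by agroclim derive from :class:`AgroclimError`,
so callers can catch one base class at pipeline boundaries.
"""


class AgroclimError(Exception):
    """Base class for all agroclim errors."""


class ConfigurationError(AgroclimError):
    """An invalid configuration field; the message names the field."""


class FormatError(AgroclimError):
    """A file does not conform to the expected dialect (e.g. missing columns)."""


class ValidationError(AgroclimError):
    """Data violates a structural invariant (e.g. a gap in a daily series)."""


class CoverageError(AgroclimError):
    """A requested window or slice is not covered by the available series."""


class AlignmentError(AgroclimError):
    """Two per-cell inputs do not refer to the same set of cells."""


class FitError(AgroclimError):
    """A statistical fit is impossible or degenerate for the given records."""


class InputError(AgroclimError):
    """An input value is outside the domain of an operation."""
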