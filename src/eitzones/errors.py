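"""Exception hierarchy.

All package errors derive from :class:`EitError` so callers can catch one
type; subclasses distinguish file-format problems, configuration problems,
breath-detection failures and degenerate images.
"""


class EitError(Exception):
    """Base class for all eitzones errors."""


class FormatError(EitError, ValueError):
    """A data file violates the expected layout (row length, non-numeric cell)."""


class ConfigError(EitError, ValueError):
    """Missing or inconsistent metadata / configuration."""


class ValidationError(EitError, ValueError):
    """A domain object violates one of its invariants."""


class DetectionError(EitError, RuntimeError):
    """Breath detection could not find usable respiratory extrema."""


class NoPositiveSignalError(EitError, ValueError):
    """An image has no positive pixels, so a relative threshold is meaningless."""
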