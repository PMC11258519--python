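"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`EndofluencyError`, so callers (and the CLI) can catch one type.
"""


class EndofluencyError(Exception):
    """Base class for all errors raised by endofluency."""


class InputError(EndofluencyError):
    """An input source is missing or undecodable."""


class ConfigurationError(EndofluencyError):
    """A configuration value is missing, inconsistent, or out of range."""


class ValidationError(EndofluencyError):
    """Data violates a documented invariant (overlaps, bad intervals, ...)."""


class ParseError(EndofluencyError):
    """A file could not be parsed; message carries the location when known."""


class CalibrationError(EndofluencyError):
    """Color calibration cannot proceed (e.g. a degenerate pixel sample)."""


class GenerationError(EndofluencyError):
    """A synthetic schedule cannot be generated under the given constraints."""
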