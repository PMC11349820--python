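"""Exception hierarchy shared across the package."""


class EVPlanktonError(Exception):
    """Base class for all errors raised by evplankton."""


class ParseError(EVPlanktonError):
    """A file could not be parsed under the named dialect.

    Carries the 1-based line (or record) number of the first offending row.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class OrderingError(EVPlanktonError):
    """Event timestamps decreased; input is corrupt and is not re-sorted."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class BoundsError(EVPlanktonError):
    """Event coordinates fall outside the sensor geometry."""


class ConfigError(EVPlanktonError):
    """Invalid configuration parameter."""


class InsufficientDataError(EVPlanktonError):
    """A track is too short (or too degenerate) for the requested quantity."""
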