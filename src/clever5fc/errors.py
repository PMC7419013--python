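"""Exception types shared across the package."""


class Clever5fcError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(Clever5fcError, ValueError):
    """A parameter is outside its documented domain."""


class UndefinedRateError(Clever5fcError, ValueError):
    """A control-derived rate cannot be computed (no qualifying reads/sites)."""


class ConfigurationError(Clever5fcError, ValueError):
    """Inconsistent or incomplete run configuration."""


class ParseError(Clever5fcError, ValueError):
    """A malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
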