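"""Exception types shared across the package."""


class MethdivError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MethdivError, ValueError):
    """A malformed line or field in an input file.

    Carries the offending file path and 1-based line number when known.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ValidationError(MethdivError, ValueError):
    """Input data violates a documented invariant (e.g. negative counts)."""


class ConfigurationError(MethdivError, ValueError):
    """A parameter or group definition is outside its documented domain."""
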