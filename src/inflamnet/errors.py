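"""Exception types shared across the package."""


class InflamnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(InflamnetError, ValueError):
    """A parameter or configuration value is outside its documented domain."""


class InputError(InflamnetError, ValueError):
    """Input data violates a precondition (empty group, missing focus gene, ...)."""


class ParseError(InflamnetError, ValueError):
    """A text input file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndefinedFitError(InflamnetError, ValueError):
    """A regression/correlation is undefined for the given data (e.g. a regular graph)."""
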