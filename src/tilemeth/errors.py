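"""Exception hierarchy shared across the package."""


class TilemethError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TilemethError, ValueError):
    """A parameter is outside its admissible range."""


class ValidationError(TilemethError, ValueError):
    """Structured input (sample sheet, region set, result table) fails its contract."""


class InsufficientDataError(TilemethError, ValueError):
    """Too few observations to compute the requested quantity."""


class ParseError(TilemethError, ValueError):
    """A text input could not be parsed; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
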