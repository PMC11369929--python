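"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A model or run parameter is outside its admissible range."""


class InvalidInputError(ValueError):
    """An input series, state or file does not satisfy its contract."""


class InsufficientDataError(InvalidInputError):
    """Too few data points for the requested estimate."""


class EstimationError(RuntimeError):
    """An estimator could not locate the feature it was asked for."""


class ParseError(InvalidInputError):
    """A text artifact violates its format; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
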