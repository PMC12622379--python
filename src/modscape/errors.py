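"""Exception hierarchy shared across the package."""


class ModscapeError(Exception):
    """Base class for all package errors."""


class ValidationError(ModscapeError):
    """Input data violates a documented invariant (bad residue, duplicate id,
    inconsistent counts, out-of-range parameter)."""


class ParseError(ModscapeError):
    """A file could not be parsed; carries a line number where applicable."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DegenerateInputError(ModscapeError):
    """The requested statistic is undefined for this input (e.g. a power-law
    fit on constant degrees)."""
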