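"""Exception hierarchy shared across the package.

Validation errors (bad user input, malformed files, impossible selections)
are distinguished from runtime failures so the command-line layer can map
them onto stable exit codes.
"""


class RdcRefineError(Exception):
    """Base class for all package errors."""


class ValidationError(RdcRefineError, ValueError):
    """Invalid input: malformed file, bad parameter, empty selection."""


class ParseError(ValidationError):
    """A text input could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class MappingError(ValidationError):
    """A residue/atom selection could not be matched between structures."""

    def __init__(self, message: str, missing=()):
        self.missing = tuple(missing)
        if self.missing:
            message = f"{message} (unmatched: {list(self.missing)})"
        super().__init__(message)


class InsufficientDataError(ValidationError):
    """Too few records/atoms to perform a fit."""


class DegenerateGeometryError(ValidationError):
    """Geometry does not constrain the requested fit (rank deficiency)."""


class RefinementError(RdcRefineError, RuntimeError):
    """A refinement run failed mid-course; carries the increment index."""

    def __init__(self, message: str, increment: int | None = None):
        self.increment = increment
        if increment is not None:
            message = f"increment {increment}: {message}"
        super().__init__(message)
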