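"""Exception hierarchy."""


class ShiftProfilerError(Exception):
    """Base class for package errors."""


class ConfigurationError(ShiftProfilerError):
    """Invalid configuration or malformed/incomplete input layout."""


class InputError(ShiftProfilerError):
    """Invalid value passed to an operation."""


class RowParseError(InputError):
    """A data row failed to parse; carries the 0-based row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class EmptyInputError(InputError):
    """An operation that requires at least one record received none."""
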