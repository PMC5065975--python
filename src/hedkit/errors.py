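"""Exception types for hedkit."""

from __future__ import annotations

__all__ = ["HedError", "SchemaError", "HedSyntaxError"]


class HedError(Exception):
    """Base class for all hedkit errors."""


class SchemaError(HedError):
    """A schema file or object violates the schema structure rules."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class HedSyntaxError(HedError):
    """An annotation string violates the HED string grammar.

    ``position`` is the 0-based character offset of the offending
    delimiter (or of the end of the string for truncation errors).
    """

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at position {position})")
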