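"""Issue records shared by schema self-checks and annotation validation.

An :class:`Issue` is one finding about a schema, a tag, an annotation
string, or an event-table cell.  Severities partition a report into the
four-output contract used throughout the toolset: *errors* (must fix),
*warnings* (style/convention), and *extensions* (tags not in the
vocabulary but hanging from places where user extension is allowed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = ["Severity", "Issue", "ISSUE_CODES"]


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"
    EXTENSION = "extension"


#: The fixed registry of issue codes.  Every Issue carries one of these.
ISSUE_CODES = frozenset(
    {
        "UNKNOWN_TAG",        # tag path does not resolve in the schema
        "REQUIRED_MISSING",   # no tag under a required node (e.g. /Event/Category)
        "RECOMMENDED_MISSING",  # no tag under a recommended node
        "UNIT_INVALID",       # value's unit not in the node's unit class
        "NOT_NUMERIC",        # numeric-valued node received a non-number
        "VALUE_FORBIDDEN",    # value hangs off a node that takes no value
        "UNIQUE_VIOLATED",    # unique node prefixes more than one tag
        "CHILD_REQUIRED",     # node requires a child/value but has none
        "LABEL_TOO_LONG",     # /Event/Label identifier at or past 20 characters
        "SYNTAX",             # annotation string could not be parsed
        "STRUCTURE",          # table row is missing a referenced column
        "SCHEMA",             # schema self-check finding
        "EXTENSION",          # tag extends the vocabulary in an allowed place
    }
)


@dataclass
class Issue:
    """One validation finding.

    ``row`` and ``column`` are 1-based positions in a tab-separated event
    table (the header line, when present, counts as row 1) and are unset
    for findings about a bare string or schema.
    """

    severity: Severity
    code: str
    message: str
    tag_text: str = ""
    row: Optional[int] = None
    column: Optional[int] = None

    def __post_init__(self) -> None:
        if self.code not in ISSUE_CODES:
            raise ValueError(f"unknown issue code {self.code!r}")
        if isinstance(self.severity, str):
            self.severity = Severity(self.severity)

    def located(self, row: Optional[int], column: Optional[int]) -> "Issue":
        """Copy of this issue annotated with a table position."""
        return Issue(self.severity, self.code, self.message, self.tag_text, row, column)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = ""
        if self.row is not None:
            where = f" [row {self.row}" + (
                f", col {self.column}]" if self.column is not None else "]"
            )
        tag = f" ({self.tag_text})" if self.tag_text else ""
        return f"{self.severity.value.upper()} {self.code}: {self.message}{tag}{where}"
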