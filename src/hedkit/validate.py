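"""Validation of HED annotations against a schema, and remapping.

The central contract mirrors the four-output shape used by the
HEDTools spreadsheet workflow: validating a tag list or an event table
yields **errors**, **warnings**, **extensions** (tags hanging from
places where user extension is allowed), and a **remap** list — the
sorted unique invalid tags, from which a correction table can be built
and applied across a whole file in one step.

Checks performed per tag: unknown paths, values on nodes that take
none, non-numeric values on numeric nodes, units outside the node's
unit class, missing required children, and over-long ``/Event/Label``
identifiers (the label is a short study-local handle, less than 20
characters; longer labels draw a warning, not an error).  Per string:
the required ``/Event/Category`` and ``/Event/Label`` tags, the
recommended ``/Event/Description`` tag, and ``unique``-attributed
nodes prefixing more than one tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .errors import HedError, HedSyntaxError
from .issues import Issue, Severity
from .schema import HedSchema, MatchKind, SchemaNode, join_path, locate
from .strings import HedString, HedTag, parse, parse_value, serialize

__all__ = [
    "ValidationReport",
    "RemapTable",
    "validate_tag",
    "validate_string",
    "validate_event_table",
    "apply_remap",
    "translate_tags",
    "translate_tag",
]

#: /Event/Label values at or beyond this many characters draw a warning.
LABEL_MAX = 19


@dataclass
class ValidationReport:
    """Errors, warnings, extensions, and the unique-invalid-tag remap list."""

    errors: List[Issue] = field(default_factory=list)
    warnings: List[Issue] = field(default_factory=list)
    extensions: List[Issue] = field(default_factory=list)

    def add(self, issue: Issue) -> None:
        {
            Severity.ERROR: self.errors,
            Severity.WARNING: self.warnings,
            Severity.EXTENSION: self.extensions,
        }[issue.severity].append(issue)

    def extend(self, issues: Iterable[Issue]) -> None:
        for issue in issues:
            self.add(issue)

    @property
    def remap(self) -> List[str]:
        """Sorted unique texts of tags flagged UNKNOWN_TAG."""
        return sorted({i.tag_text for i in self.errors if i.code == "UNKNOWN_TAG"})

    @property
    def is_clean(self) -> bool:
        return not self.errors

    def all_issues(self) -> List[Issue]:
        return [*self.errors, *self.warnings, *self.extensions]

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for issue in self.all_issues():
            out[issue.code] = out.get(issue.code, 0) + 1
        return out

    def to_dict(self) -> dict:
        def issue_dict(i: Issue) -> dict:
            return {
                "severity": i.severity.value,
                "code": i.code,
                "message": i.message,
                "tag": i.tag_text,
                "row": i.row,
                "column": i.column,
            }

        return {
            "errors": [issue_dict(i) for i in self.errors],
            "warnings": [issue_dict(i) for i in self.warnings],
            "extensions": [issue_dict(i) for i in self.extensions],
            "remap": self.remap,
        }


# ---------------------------------------------------------------------------
# tag- and string-level validation


def _looks_like_value(text: str) -> bool:
    """Heuristic: does this segment read as a supplied value?

    Bare numbers, symbol-prefixed numbers ("$10"), and "<number> <unit>"
    shapes count; ordinary words do not.
    """
    from .strings import _NUMBER_RE  # shared numeric grammar

    text = text.strip()
    if _NUMBER_RE.match(text):
        return True
    if text and not text[0].isalnum() and _NUMBER_RE.match(text[1:].strip()):
        return True
    if " " in text:
        head = text.rsplit(" ", 1)[0].strip()
        if _NUMBER_RE.match(head):
            return True
    return False


def validate_tag(tag: HedTag, schema: HedSchema) -> List[Issue]:
    """Validate one tag; the outcome of schema resolution is cached on it."""
    issues: List[Issue] = []
    match = locate(schema, tag.text)
    tag.match = match

    if match.kind is MatchKind.MISS:
        if (
            match.node is not None
            and len(match.extension_segments) == 1
            and _looks_like_value(match.extension_segments[0])
        ):
            issues.append(
                Issue(
                    Severity.ERROR,
                    "VALUE_FORBIDDEN",
                    f"node {match.node.path} takes no value and allows no extension",
                    tag.text,
                )
            )
        else:
            issues.append(
                Issue(Severity.ERROR, "UNKNOWN_TAG", "tag not in the schema", tag.text)
            )
        return issues

    if match.kind is MatchKind.EXTENSION:
        issues.append(
            Issue(
                Severity.EXTENSION,
                "EXTENSION",
                f"extends {match.node.path} with "
                f"{join_path(match.extension_segments)}",
                tag.text,
            )
        )
        return issues

    if match.kind is MatchKind.VALUE:
        node = match.node
        value_node = node.takes_value_child
        value = match.value or ""
        tag.value = value
        attrs = value_node.attributes
        unit_class = (
            schema.unit_classes.get(attrs.unit_class) if attrs.unit_class else None
        )
        if unit_class is not None:
            number, unit = parse_value(value, unit_class)
            if number is None:
                issues.append(
                    Issue(
                        Severity.ERROR,
                        "NOT_NUMERIC",
                        f"value {value!r} under unit class "
                        f"{unit_class.name!r} is not numeric",
                        tag.text,
                    )
                )
            elif unit not in unit_class.allowed_units:
                issues.append(
                    Issue(
                        Severity.ERROR,
                        "UNIT_INVALID",
                        f"unit {unit!r} not in unit class {unit_class.name!r} "
                        f"(allowed: {', '.join(unit_class.allowed_units)})",
                        tag.text,
                    )
                )
            else:
                tag.numeric_value, tag.unit = number, unit
        elif attrs.is_numeric:
            number, _ = parse_value(value, numeric_required=True)
            if number is None:
                issues.append(
                    Issue(
                        Severity.ERROR,
                        "NOT_NUMERIC",
                        f"value {value!r} is not numeric",
                        tag.text,
                    )
                )
            else:
                tag.numeric_value = number
        if node.path.lower() == "/event/label" and len(value) > LABEL_MAX:
            issues.append(
                Issue(
                    Severity.WARNING,
                    "LABEL_TOO_LONG",
                    f"label {value!r} has {len(value)} characters; "
                    f"labels are short (<20 character) identifiers",
                    tag.text,
                )
            )
        return issues

    # exact match
    node = match.node
    if node.attributes.child_required:
        issues.append(
            Issue(
                Severity.ERROR,
                "CHILD_REQUIRED",
                f"{node.path} requires a child value",
                tag.text,
            )
        )
    return issues


def _descends(tag: HedTag, node: SchemaNode) -> bool:
    want = tuple(s.lower() for s in node.path.split("/") if s)
    have = tuple(s.lower() for s in tag.segments)
    return len(have) >= len(want) and have[: len(want)] == want


def _string_level_issues(tags: Sequence[HedTag], schema: HedSchema) -> List[Issue]:
    issues: List[Issue] = []
    for node in schema._required:
        if not any(_descends(t, node) for t in tags):
            issues.append(
                Issue(
                    Severity.ERROR,
                    "REQUIRED_MISSING",
                    f"annotation has no {node.path} tag",
                    node.path,
                )
            )
    for node in schema._recommended:
        if not any(_descends(t, node) for t in tags):
            issues.append(
                Issue(
                    Severity.WARNING,
                    "RECOMMENDED_MISSING",
                    f"annotation has no {node.path} tag",
                    node.path,
                )
            )
    for node in schema._unique:
        hits = [t for t in tags if _descends(t, node)]
        if len(hits) > 1:
            issues.append(
                Issue(
                    Severity.ERROR,
                    "UNIQUE_VIOLATED",
                    f"{node.path} is unique but prefixes {len(hits)} tags",
                    hits[1].text,
                )
            )
    return issues


def validate_string(hs: HedString, schema: HedSchema) -> ValidationReport:
    """Validate one annotation string: per-tag plus string-level checks."""
    report = ValidationReport()
    for tag in hs.tags:
        report.extend(validate_tag(tag, schema))
    report.extend(_string_level_issues(hs.tags, schema))
    return report


# ---------------------------------------------------------------------------
# event tables


def validate_event_table(
    rows: Sequence[Sequence[str]],
    id_column: int,
    tag_columns: Sequence[int],
    has_header: bool,
    schema: HedSchema,
) -> ValidationReport:
    """Validate the tag columns of an event table.

    ``rows`` are pre-split cells; ``id_column`` and ``tag_columns`` are
    1-based, matching the spreadsheet convention.  Issues carry the
    1-based file row (the header, when present, is row 1 and skipped)
    and the column of the offending cell; string-level issues are
    charged to the first tag column.  The remap list aggregates over
    the whole table.  A row missing a referenced column yields a
    STRUCTURE error and validation continues.
    """
    report = ValidationReport()
    needed = max([id_column, *tag_columns])
    for rownum, row in enumerate(rows, start=1):
        if has_header and rownum == 1:
            continue
        if len(row) < needed:
            report.add(
                Issue(
                    Severity.ERROR,
                    "STRUCTURE",
                    f"row has {len(row)} columns, needs {needed}",
                    row=rownum,
                )
            )
            continue
        tags: List[HedTag] = []
        any_cell = False
        for col in tag_columns:
            cell = row[col - 1].strip()
            if not cell:
                continue
            any_cell = True
            try:
                hs = parse(cell)
            except HedSyntaxError as exc:
                report.add(
                    Issue(
                        Severity.ERROR,
                        "SYNTAX",
                        str(exc),
                        cell,
                        row=rownum,
                        column=col,
                    )
                )
                continue
            for tag in hs.tags:
                for issue in validate_tag(tag, schema):
                    report.add(issue.located(rownum, col))
            tags.extend(hs.tags)
        if any_cell:
            for issue in _string_level_issues(tags, schema):
                report.add(issue.located(rownum, tag_columns[0]))
    return report


# ---------------------------------------------------------------------------
# remapping and translation


@dataclass
class RemapTable:
    """Correspondence from invalid tag text to its corrected tag.

    Keys match case-insensitively on whole canonical tag text (for
    :func:`apply_remap`) or by longest path prefix (for
    :func:`translate_tags`).  Values are single tags.
    """

    entries: Dict[str, HedTag] = field(default_factory=dict)

    @staticmethod
    def _key(text: str) -> str:
        return HedTag.from_text(text).text.lower()

    def put(self, bad: str, good: str) -> None:
        key = self._key(bad)
        if key in self.entries:
            raise HedError(f"duplicate remap key {bad!r}")
        self.entries[key] = HedTag.from_text(good)

    def get(self, tag: HedTag) -> Optional[HedTag]:
        return self.entries.get(tag.text.lower())

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "RemapTable":
        table = cls()
        for bad, good in pairs:
            table.put(bad, good)
        return table

    @classmethod
    def from_tsv(cls, text: str) -> "RemapTable":
        """Load a two-column TSV (invalid tag, corrected tag)."""
        table = cls()
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise HedError(f"remap line {lineno} needs two tab-separated columns")
            table.put(parts[0].strip(), parts[1].strip())
        return table

    def to_tsv(self) -> str:
        return (
            "".join(f"{key}\t{tag.text}\n" for key, tag in sorted(self.entries.items()))
        )

    def check(self, schema: HedSchema) -> List[Issue]:
        """Validate all replacement tags against a schema."""
        issues: List[Issue] = []
        for tag in self.entries.values():
            issues.extend(validate_tag(HedTag(tag.segments), schema))
        return issues


def _rewrite_cell(cell: str, rewrite) -> str:
    """Parse a cell, rewrite each tag, reserialize.

    Cells that do not parse are left untouched (they surface as SYNTAX
    issues in validation, not here).
    """
    try:
        hs = parse(cell)
    except HedSyntaxError:
        return cell
    new_elements = []
    for el in hs.elements:
        if isinstance(el, HedTag):
            new_elements.append(rewrite(el))
        else:
            new_elements.append(
                type(el)(
                    tuple(tuple(rewrite(t) for t in clause) for clause in el.clauses)
                )
            )
    return serialize(HedString(tuple(new_elements)))


def apply_remap(
    rows: Sequence[Sequence[str]],
    tag_columns: Sequence[int],
    table: RemapTable,
) -> List[List[str]]:
    """Replace every whole-tag occurrence of a remap key in the tag columns.

    Matching is case-insensitive on the canonical tag text; tags absent
    from the table pass through unchanged.  Idempotent whenever no
    replacement value is itself a key.
    """

    def rewrite(tag: HedTag) -> HedTag:
        hit = table.get(tag)
        return HedTag(hit.segments) if hit is not None else tag

    out: List[List[str]] = []
    for row in rows:
        new_row = list(row)
        for col in tag_columns:
            if col - 1 < len(new_row) and new_row[col - 1].strip():
                new_row[col - 1] = _rewrite_cell(new_row[col - 1].strip(), rewrite)
        out.append(new_row)
    return out


def translate_tag(tag: HedTag, table: RemapTable) -> HedTag:
    """Rewrite a tag by its longest matching key prefix.

    Unlike :func:`apply_remap`'s whole-tag matching, translation maps a
    vocabulary *subtree*: a key ``/A/B`` applied to ``/A/B/C`` yields
    the replacement with ``/C`` re-appended.  Used for carrying
    annotations across vocabulary versions.
    """
    lowered = tuple(s.lower() for s in tag.segments)
    for k in range(len(lowered), 0, -1):
        key = join_path(lowered[:k])
        hit = table.entries.get(key)
        if hit is not None:
            return HedTag(hit.segments + tag.segments[k:])
    return tag


def translate_tags(
    rows: Sequence[Sequence[str]],
    tag_columns: Sequence[int],
    table: RemapTable,
) -> List[List[str]]:
    """Longest-prefix translation over all tag columns of a table."""

    def rewrite(tag: HedTag) -> HedTag:
        return translate_tag(tag, table)

    out: List[List[str]] = []
    for row in rows:
        new_row = list(row)
        for col in tag_columns:
            if col - 1 < len(new_row) and new_row[col - 1].strip():
                new_row[col - 1] = _rewrite_cell(new_row[col - 1].strip(), rewrite)
        out.append(new_row)
    return out
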