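"""Event tables and tag maps: reading, writing, and code-level tagging.

Events live in tab-separated tables with one identifier column — a
laboratory event *code* (``square``, ``rt``) or an event *latency* in
the recording — plus one or more columns of HED tags.  A *tag map*
stores the correspondence from event codes to full annotations, built
once per study and then applied to every event file in a collection
(``tag_directory``).

An event's effective annotation is the union of its code-level tags
(from the map) and its instance-level tags (recorded with the event),
with duplicates removed after normalization, so repeated tagging is
idempotent.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, IO, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .errors import HedError, HedSyntaxError
from .strings import HedString, normalize, parse, serialize
from .strings import _NUMBER_RE
from .schema import HedSchema

__all__ = [
    "EventRecord",
    "EventTable",
    "TableSpec",
    "TagMap",
    "TagSummary",
    "FileSummary",
    "read_events_tsv",
    "write_events_tsv",
    "load_tagmap",
    "save_tagmap",
    "apply_tagmap",
    "tag_directory",
    "split_rows",
]

Source = Union[str, Path, IO[str]]


def _read_text(source: Source) -> str:
    """Accept literal TSV text, a path, or an open file."""
    if hasattr(source, "read"):
        return source.read()  # type: ignore[union-attr]
    if isinstance(source, Path):
        return source.read_text()
    if not source.strip() or "\n" in source or "\t" in source:
        return source
    return Path(source).read_text()


def split_rows(text: str) -> List[List[str]]:
    """Split TSV text into rows of cells (trailing blank lines dropped)."""
    lines = text.split("\n")
    while lines and not lines[-1].strip():
        lines.pop()
    return [line.split("\t") for line in lines]


@dataclass
class TableSpec:
    """Column layout and latency convention of an event table (1-based)."""

    id_column: int = 1
    tag_columns: Tuple[int, ...] = (2,)
    has_header: bool = False
    latency_unit: str = "seconds"  # or "samples"
    sampling_rate: Optional[float] = None  # Hz, required for samples
    #: Optional separate latency column for tables identifying events by
    #: both a code (id column) and a time; None = the id column carries
    #: either a code or a latency.
    latency_column: Optional[int] = None

    def __post_init__(self) -> None:
        self.tag_columns = tuple(self.tag_columns)
        if self.latency_unit not in ("seconds", "samples"):
            raise ValueError(f"latency_unit must be seconds|samples, got {self.latency_unit!r}")
        if self.latency_unit == "samples" and not self.sampling_rate:
            raise ValueError("latency in samples requires a sampling rate")


@dataclass
class EventRecord:
    """One event: an identifier plus its code- and instance-level tags."""

    identifier: str
    code: Optional[str] = None
    latency_seconds: Optional[float] = None
    code_tags: Optional[HedString] = None
    instance_tags: Optional[HedString] = None

    def __post_init__(self) -> None:
        if self.code is None and self.latency_seconds is None:
            raise ValueError("event needs a code or a latency")

    def effective_tags(self, schema: Optional[HedSchema] = None) -> Optional[HedString]:
        """Union of code- and instance-level tags, deduplicated.

        The union is normalized, so its element order is the canonical
        normalization order and identical annotations collapse.
        """
        parts = [hs for hs in (self.code_tags, self.instance_tags) if hs is not None]
        if not parts:
            return None
        combined = HedString(tuple(el for hs in parts for el in hs.elements))
        merged = parse(normalize(combined, schema))
        seen = set()
        deduped = []
        for el in merged.elements:
            text = str(el)
            if text not in seen:
                seen.add(text)
                deduped.append(el)
        return HedString(tuple(deduped))


@dataclass
class EventTable:
    """Ordered event records plus the column layout they came from."""

    records: List[EventRecord] = field(default_factory=list)
    header: Optional[List[str]] = None
    spec: TableSpec = field(default_factory=TableSpec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        """Flat view for analysis: identifier, latency, code, tags."""
        return pd.DataFrame(
            {
                "identifier": [r.identifier for r in self.records],
                "latency_seconds": [r.latency_seconds for r in self.records],
                "code": [r.code for r in self.records],
                "tags": [
                    serialize(r.effective_tags()) if r.effective_tags() else ""
                    for r in self.records
                ],
            }
        )


def read_events_tsv(
    source: Source,
    id_column: int = 1,
    tag_columns: Sequence[int] = (2,),
    has_header: bool = False,
    latency_unit: str = "seconds",
    sampling_rate: Optional[float] = None,
    latency_column: Optional[int] = None,
) -> EventTable:
    """Read a tab-separated event table.

    Numeric identifiers are read as latencies (converted from samples
    to seconds by division by ``sampling_rate`` when
    ``latency_unit="samples"``); non-numeric identifiers are event
    codes.  With a separate ``latency_column`` the identifier column
    always carries the code and latencies come from that column.
    Multiple tag columns are concatenated with commas and parsed as
    one annotation.  A ragged row raises a structural error naming the
    row.
    """
    spec = TableSpec(
        id_column, tuple(tag_columns), has_header, latency_unit, sampling_rate,
        latency_column,
    )
    rows = split_rows(_read_text(source))
    header: Optional[List[str]] = None
    records: List[EventRecord] = []
    needed = max([id_column, *spec.tag_columns, *(filter(None, [latency_column]))])
    for rownum, row in enumerate(rows, start=1):
        if has_header and rownum == 1:
            header = row
            continue
        if len(row) < needed:
            raise HedError(f"row {rownum}: has {len(row)} columns, needs {needed}")
        ident = row[id_column - 1].strip()
        code = None
        latency = None
        if latency_column is not None:
            code = ident
            cell = row[latency_column - 1].strip()
            if cell:
                if not _NUMBER_RE.match(cell):
                    raise HedError(f"row {rownum}: latency {cell!r} is not a number")
                latency = float(cell)
                if latency_unit == "samples":
                    latency /= sampling_rate  # type: ignore[operator]
        elif _NUMBER_RE.match(ident):
            latency = float(ident)
            if latency_unit == "samples":
                latency /= sampling_rate  # type: ignore[operator]
        else:
            code = ident
        cells = [row[c - 1].strip() for c in spec.tag_columns]
        joined = ", ".join(cell for cell in cells if cell)
        try:
            instance = parse(joined) if joined else None
        except HedSyntaxError as exc:
            raise HedError(f"row {rownum}: bad annotation: {exc}") from exc
        records.append(EventRecord(ident, code, latency, instance_tags=instance))
    return EventTable(records, header, spec)


def write_events_tsv(table: EventTable) -> str:
    """Serialize back to TSV under the table's own column layout.

    The (possibly merged) effective annotation is written into the
    first tag column; reading the result back under the same settings
    reproduces identifiers and tags.
    """
    spec = table.spec
    width = max([spec.id_column, *spec.tag_columns, *(filter(None, [spec.latency_column]))])
    lines: List[str] = []
    if spec.has_header:
        header = table.header or [f"column_{i}" for i in range(1, width + 1)]
        lines.append("\t".join(header))
    for record in table.records:
        row = [""] * width
        row[spec.id_column - 1] = record.identifier
        if spec.latency_column is not None and record.latency_seconds is not None:
            latency = record.latency_seconds
            if spec.latency_unit == "samples":
                latency *= spec.sampling_rate  # type: ignore[operator]
            row[spec.latency_column - 1] = f"{latency:g}"
        if record.code_tags is None:
            tags = record.instance_tags
        else:
            tags = record.effective_tags()
        row[spec.tag_columns[0] - 1] = serialize(tags) if tags is not None else ""
        lines.append("\t".join(row))
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# tag maps


@dataclass
class TagMap:
    """Mapping from event codes to annotations, saved per study.

    Serialized as two-column TSV (code, HED string) with an optional
    ``#version`` comment line recording the schema version used.
    """

    entries: Dict[str, HedString] = field(default_factory=dict)
    schema_version: str = ""

    def __len__(self) -> int:
        return len(self.entries)


def load_tagmap(source: Source) -> TagMap:
    text = _read_text(source)
    tagmap = TagMap()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#version"):
            tagmap.schema_version = line[len("#version"):].strip(" :\t")
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise HedError(f"tag-map line {lineno} needs two tab-separated columns")
        code = parts[0].strip()
        if code in tagmap.entries:
            raise HedError(f"duplicate code {code!r} in tag map")
        try:
            tagmap.entries[code] = parse(parts[1].strip())
        except HedSyntaxError as exc:
            raise HedError(f"tag map entry for code {code!r}: {exc}") from exc
    return tagmap


def save_tagmap(tagmap: TagMap) -> str:
    out = []
    if tagmap.schema_version:
        out.append(f"#version {tagmap.schema_version}")
    for code, hs in tagmap.entries.items():
        out.append(f"{code}\t{serialize(hs)}")
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# applying maps


@dataclass
class TagSummary:
    """Outcome of applying a tag map to one table."""

    n_records: int = 0
    records_tagged: int = 0
    codes_unmatched: Counter = field(default_factory=Counter)


def apply_tagmap(table: EventTable, tagmap: TagMap) -> Tuple[EventTable, TagSummary]:
    """Attach code-level tags from the map to every matching record.

    Codes match case-sensitively.  Records whose code is absent from
    the map are left untagged and counted in the summary.  Idempotent.
    """
    summary = TagSummary(n_records=len(table.records))
    new_records: List[EventRecord] = []
    for record in table.records:
        if record.code is not None and record.code in tagmap.entries:
            new_records.append(replace(record, code_tags=tagmap.entries[record.code]))
            summary.records_tagged += 1
        else:
            if record.code is not None:
                summary.codes_unmatched[record.code] += 1
            new_records.append(replace(record))
    return EventTable(new_records, table.header, table.spec), summary


@dataclass
class FileSummary:
    path: str
    out_path: Optional[str] = None
    n_records: int = 0
    records_tagged: int = 0
    codes_unmatched: Counter = field(default_factory=Counter)
    error: Optional[str] = None


def tag_directory(
    paths: Sequence[Union[str, Path]],
    tagmap: TagMap,
    spec: Optional[TableSpec] = None,
    suffix: str = "_tagged",
) -> List[FileSummary]:
    """Apply a tag map to a collection of event files in one call.

    Tagged copies are written beside the inputs with ``suffix`` added
    to the stem.  Unreadable or malformed files are recorded in their
    summary and processing continues.
    """
    spec = spec or TableSpec()
    summaries: List[FileSummary] = []
    for path in paths:
        path = Path(path)
        summary = FileSummary(path=str(path))
        try:
            table = read_events_tsv(
                path,
                spec.id_column,
                spec.tag_columns,
                spec.has_header,
                spec.latency_unit,
                spec.sampling_rate,
                spec.latency_column,
            )
            tagged, tag_summary = apply_tagmap(table, tagmap)
            out_path = path.with_name(path.stem + suffix + path.suffix)
            out_path.write_text(write_events_tsv(tagged))
            summary.out_path = str(out_path)
            summary.n_records = tag_summary.n_records
            summary.records_tagged = tag_summary.records_tagged
            summary.codes_unmatched = tag_summary.codes_unmatched
        except (OSError, HedError) as exc:
            summary.error = str(exc)
        summaries.append(summary)
    return summaries
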