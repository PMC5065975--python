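"""Tag-based event selection, epoch extraction, and tag summaries.

Selection uses *prefix matching*: a query path matches a tag when its
segments equal the tag's leading segments, whole segment by whole
segment, case-insensitively.  This is the operation the semi-structured
tagging scheme is designed around — no reasoner needed, only string
comparison — and it is what makes pooling similarly-tagged events
across studies cheap.

Epochs are abstract time windows ``[latency - pre, latency + post]``
anchored at selected event latencies; clipping to recording bounds is
the caller's concern since no signal files are read here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import HedError
from .events import EventRecord, EventTable
from .schema import HedSchema, join_path, split_path
from .strings import HedString, HedTag

__all__ = [
    "TagQuery",
    "Epoch",
    "tag_matches",
    "string_matches",
    "select_events",
    "extract_epochs",
    "summarize",
]


@dataclass(frozen=True)
class TagQuery:
    """One or more tag-path prefixes, combined with any/all semantics."""

    prefixes: Tuple[str, ...]
    mode: str = "any"

    def __post_init__(self) -> None:
        if not self.prefixes:
            raise ValueError("query needs at least one prefix")
        if self.mode not in ("any", "all"):
            raise ValueError(f"mode must be any|all, got {self.mode!r}")

    @classmethod
    def of(cls, *prefixes: str, mode: str = "any") -> "TagQuery":
        return cls(tuple(prefixes), mode)


def tag_matches(tag: HedTag, prefix: str) -> bool:
    """Whole-segment, case-insensitive prefix match.

    ``/Item/Object`` matches ``/Item/Object/Vehicle/Car`` but not
    ``/Item/Objective/X``; a tag equal to the prefix matches.
    """
    want = tuple(s.lower() for s in split_path(prefix))
    if not want:
        raise ValueError("empty query prefix")
    have = tuple(s.lower() for s in tag.segments)
    return len(have) >= len(want) and have[: len(want)] == want


def string_matches(hs: HedString, query: TagQuery) -> bool:
    """Does an annotation satisfy a query?

    All tags are flattened (top level and inside every group clause).
    ``any``: some prefix matches some tag; ``all``: every prefix
    matches some tag.
    """
    tags = hs.tags
    hits = (any(tag_matches(t, p) for t in tags) for p in query.prefixes)
    return any(hits) if query.mode == "any" else all(hits)


def select_events(table: EventTable, query: TagQuery) -> List[EventRecord]:
    """Order-preserving filter of a table by its effective annotations."""
    out: List[EventRecord] = []
    for record in table.records:
        tags = record.effective_tags()
        if tags is not None and string_matches(tags, query):
            out.append(record)
    return out


@dataclass(frozen=True)
class Epoch:
    """A time window anchored at one event latency (seconds).

    ``start`` may be negative for early events; callers clip to the
    recording's bounds.
    """

    event_index: int
    start: float
    end: float
    anchor: float


def extract_epochs(
    table: EventTable,
    query: TagQuery,
    pre: float,
    post: float,
) -> List[Epoch]:
    """One epoch ``[latency - pre, latency + post]`` per selected event.

    Every selected record must carry a latency; a code-only record
    matching the query is an error naming the record.
    """
    if pre < 0 or post < 0:
        raise ValueError("pre and post must be >= 0")
    index_of = {id(r): i for i, r in enumerate(table.records)}
    epochs: List[Epoch] = []
    for record in select_events(table, query):
        if record.latency_seconds is None:
            raise HedError(
                f"event {record.identifier!r} matches the query but has no latency"
            )
        anchor = record.latency_seconds
        epochs.append(Epoch(index_of[id(record)], anchor - pre, anchor + post, anchor))
    return epochs


def summarize(
    tables: Sequence[EventTable],
    level: int,
    schema: Optional[HedSchema] = None,
) -> Dict[str, int]:
    """Count event instances per tag path truncated to ``level``.

    For each path of depth ``level``, the value is the number of event
    instances carrying at least one tag at or below that path — an
    instance counts once per path, however many of its tags fall under
    it.  Tags shallower than ``level`` contribute nothing.  When a
    schema is given, truncated paths take its capitalization.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    counts: Dict[str, int] = {}
    for table in tables:
        for record in table.records:
            tags = record.effective_tags()
            if tags is None:
                continue
            buckets = set()
            for tag in tags.tags:
                if len(tag.segments) < level:
                    continue
                truncated = tag.segments[:level]
                if schema is not None:
                    node = schema.find(join_path(truncated))
                    path = node.path if node is not None else join_path(truncated)
                else:
                    path = join_path(truncated)
                buckets.add(path)
            for path in buckets:
                counts[path] = counts.get(path, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
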