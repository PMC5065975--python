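"""HED annotation strings: parsing, serialization, normalization.

A HED string annotates one event as a comma-separated list of *tags*
(slash-delimited paths into the vocabulary) and parenthesized *groups*
of tags.  A group binds the tags to one described item — e.g. a circle
together with its color and screen position — and may be split by
tildes into up to three clauses forming a subject ~ predicate ~ object
statement ("Man ate Fish").  Parenthesis nesting is limited to one
level, which keeps every group a simple sentence.

Normalization produces the unique canonical text of an annotation:
comma lists are order-insensitive and sorted, while clause order inside
a group is meaning ("Man ate Fish" != "Fish ate Man") and is preserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

from .errors import HedSyntaxError
from .schema import HedSchema, MatchKind, PathMatch, UnitClass, join_path, split_path

__all__ = [
    "HedTag",
    "HedGroup",
    "HedString",
    "parse",
    "serialize",
    "normalize",
    "substitute",
    "parse_value",
]

_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


@dataclass(eq=False)
class HedTag:
    """One tag: an ordered sequence of path segments.

    ``value``, ``numeric_value`` and ``unit`` are filled in when the
    tag is bound to a schema node that takes a (possibly unit-classed)
    value; ``match`` caches the schema resolution.
    """

    segments: Tuple[str, ...]
    raw_text: str = ""
    match: Optional[PathMatch] = field(default=None, repr=False)
    value: Optional[str] = None
    numeric_value: Optional[float] = None
    unit: Optional[str] = None

    @classmethod
    def from_text(cls, text: str) -> "HedTag":
        segments = tuple(split_path(text))
        if not segments:
            raise ValueError(f"empty tag text {text!r}")
        return cls(segments, raw_text=text)

    @property
    def text(self) -> str:
        """Canonical text: '/'-joined segments with a leading '/'."""
        return join_path(self.segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HedTag):
            return NotImplemented
        return self.segments == other.segments

    def __hash__(self) -> int:
        return hash(self.segments)

    def __str__(self) -> str:
        return self.text


@dataclass(frozen=True)
class HedGroup:
    """A parenthesized group: 1-3 tilde clauses, each a list of tags.

    Clause order is semantically significant (subject ~ predicate ~
    object) and is never reordered.
    """

    clauses: Tuple[Tuple[HedTag, ...], ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.clauses) <= 3:
            raise ValueError("a group holds 1 to 3 tilde clauses")
        if any(not clause for clause in self.clauses):
            raise ValueError("empty clause in group")

    @property
    def tags(self) -> Tuple[HedTag, ...]:
        """All member tags in order, across clauses."""
        return tuple(tag for clause in self.clauses for tag in clause)

    def __str__(self) -> str:
        return (
            "("
            + " ~ ".join(", ".join(t.text for t in clause) for clause in self.clauses)
            + ")"
        )


Element = Union[HedTag, HedGroup]


@dataclass(eq=False)
class HedString:
    """A parsed annotation: ordered top-level tags and groups."""

    elements: Tuple[Element, ...]
    source_text: str = ""

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HedString):
            return NotImplemented
        return self.elements == other.elements

    @property
    def tags(self) -> Tuple[HedTag, ...]:
        """All tags flattened: top level plus every group clause."""
        out: List[HedTag] = []
        for el in self.elements:
            if isinstance(el, HedTag):
                out.append(el)
            else:
                out.extend(el.tags)
        return tuple(out)

    @property
    def groups(self) -> Tuple[HedGroup, ...]:
        return tuple(el for el in self.elements if isinstance(el, HedGroup))

    def value_of(self, prefix: str) -> Optional[str]:
        """The trailing value of the first tag extending ``prefix``.

        E.g. ``value_of("/Event/Label")`` on a string containing
        ``/Event/Label/Target`` returns ``"Target"``.
        """
        want = tuple(s.lower() for s in split_path(prefix))
        for tag in self.tags:
            have = tuple(s.lower() for s in tag.segments)
            if len(have) > len(want) and have[: len(want)] == want:
                return "/".join(tag.segments[len(want):])
        return None

    def __str__(self) -> str:
        return serialize(self)


# ---------------------------------------------------------------------------
# parsing


def parse(text: str) -> HedString:
    """Parse annotation text into a :class:`HedString`.

    Commas split top-level elements, ``(...)`` delimits a group, and
    ``~`` splits a group into clauses.  Raises :class:`HedSyntaxError`
    (with the character position) for unbalanced or nested parentheses,
    a tilde outside a group, more than three clauses, or empty elements.
    """
    n = len(text)

    def skip_ws(i: int) -> int:
        while i < n and text[i].isspace():
            i += 1
        return i

    def read_tag(i: int) -> Tuple[HedTag, int]:
        j = i
        while j < n and text[j] not in ",()~":
            j += 1
        raw = text[i:j].strip()
        if not raw or not split_path(raw):
            raise HedSyntaxError("empty tag", i)
        return HedTag.from_text(raw), j

    def read_group(i: int) -> Tuple[HedGroup, int]:
        opened = i
        i += 1
        clauses: List[List[HedTag]] = [[]]
        expect_tag = True
        while True:
            i = skip_ws(i)
            if i >= n:
                raise HedSyntaxError("unbalanced '('", opened)
            c = text[i]
            if c == ")":
                if expect_tag:
                    raise HedSyntaxError("empty element in group", i)
                return HedGroup(tuple(tuple(cl) for cl in clauses)), i + 1
            if c == "(":
                raise HedSyntaxError("nesting limited to one level", i)
            if c == "~":
                if expect_tag:
                    raise HedSyntaxError("empty clause", i)
                if len(clauses) >= 3:
                    raise HedSyntaxError("more than 3 tilde clauses", i)
                clauses.append([])
                expect_tag = True
                i += 1
                continue
            if c == ",":
                if expect_tag:
                    raise HedSyntaxError("empty element between commas", i)
                expect_tag = True
                i += 1
                continue
            tag, i = read_tag(i)
            clauses[-1].append(tag)
            expect_tag = False

    elements: List[Element] = []
    i = skip_ws(0)
    if i >= n:
        raise HedSyntaxError("empty HED string", 0)
    expect_element = True
    while i < n:
        i = skip_ws(i)
        if i >= n:
            break
        c = text[i]
        if expect_element:
            if c == "(":
                group, i = read_group(i)
                elements.append(group)
                expect_element = False
            elif c == ",":
                raise HedSyntaxError("empty element between commas", i)
            elif c == "~":
                raise HedSyntaxError("tilde outside a parenthesized group", i)
            elif c == ")":
                raise HedSyntaxError("unbalanced ')'", i)
            else:
                tag, i = read_tag(i)
                elements.append(tag)
                expect_element = False
        else:
            if c == ",":
                expect_element = True
                i += 1
            elif c == ")":
                raise HedSyntaxError("unbalanced ')'", i)
            elif c == "~":
                raise HedSyntaxError("tilde outside a parenthesized group", i)
            else:
                raise HedSyntaxError(f"expected ',' before {c!r}", i)
    if expect_element:
        raise HedSyntaxError("empty element after trailing comma", n - 1 if n else 0)
    return HedString(tuple(elements), source_text=text)


def serialize(hs: HedString) -> str:
    """Canonical text: ", " between elements, " ~ " between clauses."""
    return ", ".join(str(el) if isinstance(el, HedGroup) else el.text for el in hs.elements)


# ---------------------------------------------------------------------------
# normalization


def _canonical_tag_text(tag: HedTag, schema: Optional[HedSchema]) -> str:
    """Case-fold a tag to the schema's capitalization (else lower-case).

    Known segments take the schema's spelling; a trailing wildcard
    value is kept verbatim; unknown/extension segments are lower-cased
    so that normalization stays deterministic.
    """
    if schema is None:
        return tag.text.lower()
    segments: List[str] = []
    candidates = schema.roots
    node = None
    depth = 0
    for seg in tag.segments:
        nxt = None
        lowered = seg.lower()
        for cand in candidates:
            if cand.name.lower() == lowered:
                nxt = cand
                break
        if nxt is None:
            break
        node = nxt
        segments.append(node.name)
        depth += 1
        candidates = node.children
    rest = tag.segments[depth:]
    if rest:
        if node is not None and len(rest) == 1 and node.takes_value_child is not None:
            segments.append(rest[0])  # a supplied value: keep as typed
        else:
            segments.extend(seg.lower() for seg in rest)
    return join_path(segments)


def normalize(hs: HedString, schema: Optional[HedSchema] = None) -> str:
    """Unique canonical text of an annotation.

    Tags are case-folded to the schema's capitalization (lower-case
    when unknown); every comma list — the top level and each clause —
    is sorted case-insensitively; top-level single tags precede groups;
    clause order inside groups is preserved.  Idempotent:
    ``normalize(parse(normalize(x))) == normalize(x)``.
    """

    def sort_key(text: str) -> str:
        return text.lower()

    tag_texts = sorted(
        (
            _canonical_tag_text(el, schema)
            for el in hs.elements
            if isinstance(el, HedTag)
        ),
        key=sort_key,
    )
    group_texts = []
    for group in hs.groups:
        clause_texts = []
        for clause in group.clauses:
            members = sorted(
                (_canonical_tag_text(t, schema) for t in clause), key=sort_key
            )
            clause_texts.append(", ".join(members))
        group_texts.append("(" + " ~ ".join(clause_texts) + ")")
    group_texts.sort(key=sort_key)
    return ", ".join(tag_texts + group_texts)


# ---------------------------------------------------------------------------
# wildcard values


def substitute(template: str, value: str) -> HedTag:
    """Fill a '#' wildcard template with a concrete value.

    ``substitute("/Attribute/Presentation fraction/#", "0.1")`` yields
    the tag ``/Attribute/Presentation fraction/0.1``.  An empty value is
    allowed here and flagged later by validation.
    """
    tag = HedTag.from_text(template)
    if tag.segments[-1] != "#":
        raise ValueError(f"template {template!r} does not end in '#'")
    filled = HedTag(tag.segments[:-1] + (value,), raw_text=template)
    filled.value = value
    return filled


def parse_value(
    value: str,
    unit_class: Optional[UnitClass] = None,
    numeric_required: bool = False,
) -> Tuple[Optional[float], Optional[str]]:
    """Parse a wildcard value into ``(number, unit)``; never raises.

    Under a unit class the accepted shapes are ``"<number> <unit>"``
    (single space), a bare number (the class's default unit applies),
    or ``"<symbol><number>"`` for one-character symbol units such as
    ``$``.  The returned unit is *not* checked for membership in the
    class — the caller judges validity.  With ``numeric_required`` and
    no unit class only a bare number parses.  ``(None, None)`` means no
    parse.
    """
    value = value.strip()

    def as_number(text: str) -> Optional[float]:
        return float(text) if _NUMBER_RE.match(text) else None

    if unit_class is not None:
        for u in unit_class.allowed_units:
            if len(u) == 1 and not u.isalnum() and value.startswith(u):
                num = as_number(value[len(u):])
                if num is not None:
                    return num, u
        if " " in value:
            num_part, unit = value.rsplit(" ", 1)
            num = as_number(num_part.strip())
            if num is not None and unit:
                return num, unit
        num = as_number(value)
        if num is not None:
            return num, unit_class.default_unit
        return None, None
    if numeric_required:
        return as_number(value), None
    return None, None
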