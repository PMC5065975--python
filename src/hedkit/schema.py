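"""Hierarchical vocabulary (schema) model for HED annotation.

A HED schema is a forest of named nodes, up to seven levels deep, each
carrying a description and a small attribute set (``required``,
``takesValue``, ``extensionAllowed``, ...).  Value-taking positions are
marked by a child node named ``#`` (the wildcard), optionally tied to a
*unit class* — a named set of allowed measurement units with a default.

This module reads and writes two on-disk dialects:

* an XML dialect — one ``<node>`` element per vocabulary node with
  ``<name>`` and ``<description>`` children and attribute flags as XML
  attributes, followed by a trailing ``<unitClasses>`` section;
* a MediaWiki text dialect — ``'''Name'''`` headings for top-level
  nodes, ``*``-depth list items for descendants, ``{...}`` attribute
  markers and ``[...]`` description brackets.

It also resolves tag paths against the vocabulary (:func:`locate`),
including wildcard value matches and user extensions, which is the
primitive under both validation and prefix-based event search.
"""

from __future__ import annotations

import io
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

from .errors import HedError, SchemaError
from .issues import Issue, Severity

__all__ = [
    "UnitClass",
    "NodeAttributes",
    "SchemaNode",
    "HedSchema",
    "MatchKind",
    "PathMatch",
    "parse_schema_xml",
    "serialize_schema_xml",
    "parse_schema_wiki",
    "serialize_schema_wiki",
    "locate",
    "search",
    "nodes_at_level",
    "check_schema",
    "split_path",
    "join_path",
]

#: Characters that cannot appear in a node name (they are string syntax).
FORBIDDEN_NAME_CHARS = "/,()~"

# Flag attributes, in canonical serialization order, with their XML
# (lowerCamelCase) spelling mapped to the Python field name.
_FLAG_ATTRS = {
    "required": "required",
    "childRequired": "child_required",
    "unique": "unique",
    "recommended": "recommended",
    "takesValue": "takes_value",
    "isNumeric": "is_numeric",
    "extensionAllowed": "extension_allowed",
}
_VALUE_ATTRS = ("position", "type", "unitClass", "predicateType")


def split_path(path: str) -> List[str]:
    """Split a tag path into segments, tolerating a leading '/'.

    Surrounding whitespace and internal whitespace runs within a
    segment are normalized to single spaces.
    """
    path = path.strip()
    if path.startswith("/"):
        path = path[1:]
    if not path:
        return []
    return [re.sub(r"\s+", " ", seg).strip() for seg in path.split("/")]


def join_path(segments: Sequence[str]) -> str:
    """Join segments into a canonical path with a leading '/'."""
    return "/" + "/".join(segments)


@dataclass(frozen=True)
class UnitClass:
    """A named set of allowed measurement units with a default.

    The default unit is applied when a value under this class is given
    as a bare number (e.g. ``/Attribute/Duration/5`` means 5 s when the
    ``time`` class defaults to seconds).
    """

    name: str
    allowed_units: Tuple[str, ...]
    default_unit: str

    def __post_init__(self) -> None:
        if not self.allowed_units:
            raise SchemaError(f"unit class {self.name!r} has no allowed units")


@dataclass
class NodeAttributes:
    """Per-node attribute set.

    ``position`` and ``type`` are carried and round-tripped but drive no
    validation; any attribute not in the documented set is preserved
    opaquely in ``extras``.
    """

    required: bool = False
    child_required: bool = False
    unique: bool = False
    recommended: bool = False
    takes_value: bool = False
    is_numeric: bool = False
    extension_allowed: bool = False
    position: Optional[int] = None
    type: Optional[str] = None
    unit_class: Optional[str] = None
    predicate_type: str = "subclass"  # "subclass" or "property"
    extras: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.predicate_type not in ("subclass", "property"):
            raise SchemaError(
                f"predicateType must be 'subclass' or 'property', got {self.predicate_type!r}"
            )


@dataclass(eq=False)
class SchemaNode:
    """One vocabulary node: a name, a description, attributes, children."""

    name: str
    description: str = ""
    attributes: NodeAttributes = field(default_factory=NodeAttributes)
    children: List["SchemaNode"] = field(default_factory=list)

    # populated when the owning schema indexes itself
    path: str = field(default="", repr=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SchemaNode):
            return NotImplemented
        return (
            self.name == other.name
            and self.description == other.description
            and self.attributes == other.attributes
            and self.children == other.children
        )

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def takes_value_child(self) -> Optional["SchemaNode"]:
        """The '#' wildcard child of this node, if any."""
        for child in self.children:
            if child.name == "#":
                return child
        return None

    def child_named(self, name: str) -> Optional["SchemaNode"]:
        lowered = name.lower()
        for child in self.children:
            if child.name.lower() == lowered:
                return child
        return None

    def walk(self) -> Iterator["SchemaNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


class MatchKind(str, Enum):
    EXACT = "exact"
    VALUE = "valueMatch"
    EXTENSION = "extension"
    MISS = "miss"


@dataclass
class PathMatch:
    """Outcome of resolving a tag path against a schema.

    * ``exact`` — the full path names a vocabulary node.
    * ``valueMatch`` — all but the final segment names a node with a
      ``#`` wildcard child; the final segment is the supplied value.
    * ``extension`` — a strict prefix names a node that is a leaf or
      carries ``extensionAllowed``; the remaining segments are a user
      extension of the vocabulary.
    * ``miss`` — none of the above; ``node`` is the deepest valid
      ancestor (None when not even the first segment resolves).
    """

    kind: MatchKind
    node: Optional[SchemaNode]
    matched_depth: int
    extension_segments: Tuple[str, ...] = ()
    value: Optional[str] = None


class HedSchema:
    """A HED vocabulary: ordered roots plus a unit-class registry.

    The schema maintains a case-insensitive index from every
    '/'-joined path to its node; matching is case-insensitive while
    storage preserves the schema's canonical capitalization.
    """

    def __init__(
        self,
        roots: Optional[Sequence[SchemaNode]] = None,
        unit_classes: Optional[Sequence[UnitClass]] = None,
        version: str = "",
    ):
        self.version = version
        self.roots: List[SchemaNode] = list(roots or [])
        self.unit_classes: Dict[str, UnitClass] = {
            uc.name: uc for uc in (unit_classes or [])
        }
        self._index: Dict[str, SchemaNode] = {}
        self.reindex()

    # -- construction / bookkeeping ------------------------------------

    def reindex(self) -> None:
        """Rebuild the path index after structural edits."""
        self._index = {}
        for root in self.roots:
            self._index_node(root, "")
        self._required = [n for n in self.nodes() if n.attributes.required]
        self._recommended = [n for n in self.nodes() if n.attributes.recommended]
        self._unique = [n for n in self.nodes() if n.attributes.unique]

    def _index_node(self, node: SchemaNode, parent_path: str) -> None:
        node.path = f"{parent_path}/{node.name}"
        self._index[node.path.lower()] = node
        for child in node.children:
            self._index_node(child, node.path)

    def nodes(self) -> Iterator[SchemaNode]:
        """All nodes in depth-first (document) order."""
        for root in self.roots:
            yield from root.walk()

    def __len__(self) -> int:
        return len(self._index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HedSchema):
            return NotImplemented
        return (
            self.version == other.version
            and self.roots == other.roots
            and self.unit_classes == other.unit_classes
        )

    # -- lookup --------------------------------------------------------

    def find(self, path: str) -> Optional[SchemaNode]:
        """Exact (case-insensitive) path lookup; None when absent."""
        segments = split_path(path)
        if not segments:
            return None
        return self._index.get(join_path(segments).lower())

    def locate(self, path: str) -> PathMatch:
        return locate(self, path)

    def search(self, fragment: str) -> List[str]:
        return search(self, fragment)

    def nodes_at_level(self, level: int) -> List[str]:
        return nodes_at_level(self, level)

    def check(self) -> List[Issue]:
        return check_schema(self)


# ---------------------------------------------------------------------------
# path resolution


def locate(schema: HedSchema, path: str) -> PathMatch:
    """Resolve a tag path against the schema (case-insensitive).

    See :class:`PathMatch` for the four outcomes.  Matching walks the
    tree greedily: a named child always wins over the ``#`` wildcard.
    """
    segments = split_path(path)
    if not segments:
        raise ValueError("empty tag path")

    node: Optional[SchemaNode] = None
    depth = 0
    candidates = schema.roots
    for seg in segments:
        nxt = None
        lowered = seg.lower()
        for cand in candidates:
            if cand.name.lower() == lowered:
                nxt = cand
                break
        if nxt is None:
            break
        node = nxt
        depth += 1
        candidates = node.children

    remaining = tuple(segments[depth:])
    if not remaining:
        assert node is not None
        return PathMatch(MatchKind.EXACT, node, depth)
    if node is None:
        return PathMatch(MatchKind.MISS, None, 0, remaining)
    if len(remaining) == 1 and node.takes_value_child is not None:
        return PathMatch(MatchKind.VALUE, node, depth, value=remaining[0])
    if node.is_leaf or node.attributes.extension_allowed:
        return PathMatch(MatchKind.EXTENSION, node, depth, remaining)
    return PathMatch(MatchKind.MISS, node, depth, remaining)


def search(schema: HedSchema, fragment: str) -> List[str]:
    """All paths whose final segment contains ``fragment`` (case-insensitive).

    Results are ordered by path, so narrowing the fragment always
    returns a superset of a longer fragment's results.
    """
    if not fragment:
        raise ValueError("empty search fragment")
    needle = fragment.lower()
    hits = [node.path for node in schema.nodes() if needle in node.name.lower()]
    return sorted(hits, key=str.lower)


def nodes_at_level(schema: HedSchema, level: int) -> List[str]:
    """Paths of depth exactly ``level`` in document order (roots = 1)."""
    if level < 1:
        raise ValueError("level must be >= 1")
    return [
        node.path
        for node in schema.nodes()
        if len(split_path(node.path)) == level
    ]


# ---------------------------------------------------------------------------
# self-check


def check_schema(schema: HedSchema) -> List[Issue]:
    """Structural self-check of a schema object.

    Reports duplicate sibling names, dangling unit-class references,
    default units outside their class, wildcard nodes with children,
    numeric flags without ``takesValue``, and forbidden name characters.
    """
    issues: List[Issue] = []

    def schema_issue(message: str, tag: str = "") -> None:
        issues.append(Issue(Severity.ERROR, "SCHEMA", message, tag))

    for name, uc in schema.unit_classes.items():
        if uc.default_unit not in uc.allowed_units:
            schema_issue(
                f"unit class {name!r}: default unit {uc.default_unit!r} "
                f"not among allowed units {list(uc.allowed_units)}"
            )

    def visit(siblings: Sequence[SchemaNode], parent_path: str) -> None:
        seen: Dict[str, str] = {}
        for node in siblings:
            path = f"{parent_path}/{node.name}"
            lowered = node.name.lower()
            if lowered in seen:
                schema_issue(
                    f"duplicate sibling name {node.name!r} under "
                    f"{parent_path or '/'} (conflicts with {seen[lowered]!r})",
                    path,
                )
            seen[lowered] = node.name
            if node.name != "#" and any(c in node.name for c in FORBIDDEN_NAME_CHARS):
                schema_issue(f"node name {node.name!r} contains reserved characters", path)
            attrs = node.attributes
            if node.name == "#" and node.children:
                schema_issue("wildcard '#' node must not have children", path)
            if attrs.takes_value and node.name != "#":
                schema_issue("takesValue node must be named '#'", path)
            if attrs.is_numeric and not attrs.takes_value:
                schema_issue("isNumeric requires takesValue", path)
            if attrs.unit_class is not None:
                if not attrs.takes_value:
                    schema_issue("unitClass requires takesValue", path)
                if attrs.unit_class not in schema.unit_classes:
                    schema_issue(
                        f"unitClass {attrs.unit_class!r} is not in the registry", path
                    )
            visit(node.children, path)

    visit(schema.roots, "")
    return issues


def _raise_on_issues(schema: HedSchema) -> HedSchema:
    issues = check_schema(schema)
    if issues:
        raise SchemaError("; ".join(i.message for i in issues))
    return schema


# ---------------------------------------------------------------------------
# XML dialect


def parse_schema_xml(source: str) -> HedSchema:
    """Parse the XML schema dialect into a :class:`HedSchema`.

    ``source`` is the document text (or a path-like handled by the CLI
    layer).  Structural violations — duplicate siblings, dangling unit
    classes, a default unit outside its class — raise
    :class:`SchemaError`; malformed XML raises a parse error carrying
    the line number.
    """
    try:
        root = ET.fromstring(source)
    except ET.ParseError as exc:
        line, col = exc.position
        raise SchemaError(f"malformed XML: {exc.msg.split(':')[0]}", line=line) from exc
    if root.tag != "HED":
        raise SchemaError(f"expected root element <HED>, found <{root.tag}>")

    version = root.get("version", "")
    roots = [_node_from_xml(el) for el in root.findall("node")]
    unit_classes = []
    uc_section = root.find("unitClasses")
    if uc_section is not None:
        for el in uc_section.findall("unitClass"):
            name_el = el.find("name")
            default_el = el.find("defaultUnit")
            if name_el is None or default_el is None or not (name_el.text or "").strip():
                raise SchemaError("unitClass requires <name> and <defaultUnit>")
            units = tuple(
                (u.text or "").strip() for u in el.findall("units/unit")
            )
            unit_classes.append(
                UnitClass((name_el.text or "").strip(), units, (default_el.text or "").strip())
            )
    schema = HedSchema(roots, unit_classes, version=version)
    return _raise_on_issues(schema)


def _node_from_xml(el: ET.Element) -> SchemaNode:
    name_el = el.find("name")
    if name_el is None or not (name_el.text or "").strip():
        raise SchemaError("<node> element without a <name>")
    name = (name_el.text or "").strip()
    desc_el = el.find("description")
    description = (desc_el.text or "").strip() if desc_el is not None else ""

    attrs = NodeAttributes()
    for key, raw in el.attrib.items():
        if key in _FLAG_ATTRS:
            setattr(attrs, _FLAG_ATTRS[key], raw.lower() == "true")
        elif key == "position":
            attrs.position = int(raw)
        elif key == "type":
            attrs.type = raw
        elif key == "unitClass":
            attrs.unit_class = raw
        elif key == "predicateType":
            attrs.predicate_type = raw
            if raw not in ("subclass", "property"):
                raise SchemaError(f"node {name!r}: bad predicateType {raw!r}")
        else:
            attrs.extras[key] = raw

    children = [_node_from_xml(child) for child in el.findall("node")]
    return SchemaNode(name, description, attrs, children)


def serialize_schema_xml(schema: HedSchema) -> str:
    """Serialize to the XML dialect; re-parsing yields an equal schema."""
    root = ET.Element("HED")
    if schema.version:
        root.set("version", schema.version)
    for node in schema.roots:
        root.append(_node_to_xml(node))
    if schema.unit_classes:
        section = ET.SubElement(root, "unitClasses")
        for uc in schema.unit_classes.values():
            el = ET.SubElement(section, "unitClass")
            ET.SubElement(el, "name").text = uc.name
            ET.SubElement(el, "defaultUnit").text = uc.default_unit
            units = ET.SubElement(el, "units")
            for unit in uc.allowed_units:
                ET.SubElement(units, "unit").text = unit
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=False) + "\n"


def _node_to_xml(node: SchemaNode) -> ET.Element:
    el = ET.Element("node")
    attrs = node.attributes
    for xml_name, py_name in _FLAG_ATTRS.items():
        if getattr(attrs, py_name):
            el.set(xml_name, "true")
    if attrs.position is not None:
        el.set("position", str(attrs.position))
    if attrs.type is not None:
        el.set("type", attrs.type)
    if attrs.unit_class is not None:
        el.set("unitClass", attrs.unit_class)
    if attrs.predicate_type != "subclass":
        el.set("predicateType", attrs.predicate_type)
    for key in sorted(attrs.extras):
        el.set(key, attrs.extras[key])
    ET.SubElement(el, "name").text = node.name
    if node.description:
        ET.SubElement(el, "description").text = node.description
    for child in node.children:
        el.append(_node_to_xml(child))
    return el


# ---------------------------------------------------------------------------
# MediaWiki dialect

_WIKI_ROOT_RE = re.compile(r"^'''(.+?)'''\s*(.*)$")
_WIKI_ITEM_RE = re.compile(r"^(\*+)\s*(.*)$")
_WIKI_UNIT_SECTION = "== Unit classes =="


def parse_schema_wiki(source: str) -> HedSchema:
    """Parse the MediaWiki text dialect.

    ``'''Name'''`` introduces a top-level node, ``*``-depth list items
    its descendants; ``{flag, key=value}`` markers carry attributes and
    ``[...]`` brackets the description.  A list item that deepens by
    more than one level is a structure error (reported with its line
    number).  Unit classes follow a ``== Unit classes ==`` heading as
    ``* name {default=u} [u1, u2]`` items.
    """
    version = ""
    roots: List[SchemaNode] = []
    unit_classes: List[UnitClass] = []
    # stack[d] = most recent node at depth d (root = depth 1)
    stack: List[SchemaNode] = []
    in_units = False

    for lineno, raw in enumerate(source.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        if line.strip() == _WIKI_UNIT_SECTION:
            in_units = True
            continue
        if line.startswith("HED version"):
            version = line.split("=", 1)[1].strip().strip('"') if "=" in line else ""
            continue
        if in_units:
            m = _WIKI_ITEM_RE.match(line)
            if not m:
                raise SchemaError(f"unrecognized unit-class line: {line!r}", line=lineno)
            name, attrs, desc = _parse_wiki_item(m.group(2), lineno)
            units = tuple(u.strip() for u in desc.split(",")) if desc else ()
            default = attrs.extras.get("default", "")
            unit_classes.append(UnitClass(name, units, default))
            continue
        m = _WIKI_ROOT_RE.match(line)
        if m:
            name, attrs, desc = _parse_wiki_item(m.group(1) + " " + m.group(2), lineno)
            node = SchemaNode(name, desc, attrs)
            roots.append(node)
            stack = [node]
            continue
        m = _WIKI_ITEM_RE.match(line)
        if m:
            depth = len(m.group(1)) + 1  # '*' = child of a root (depth 2)
            if not stack:
                raise SchemaError("list item before any top-level node", line=lineno)
            if depth > len(stack) + 1:
                raise SchemaError(
                    f"indentation jumps {depth - len(stack)} levels", line=lineno
                )
            name, attrs, desc = _parse_wiki_item(m.group(2), lineno)
            node = SchemaNode(name, desc, attrs)
            stack[depth - 2].children.append(node)
            del stack[depth - 1:]
            stack.append(node)
            continue
        raise SchemaError(f"unrecognized line: {line!r}", line=lineno)

    schema = HedSchema(roots, unit_classes, version=version)
    return _raise_on_issues(schema)


def _parse_wiki_item(text: str, lineno: int) -> Tuple[str, NodeAttributes, str]:
    """Split a wiki item into (name, attributes, description-or-units)."""
    text = text.strip()
    attrs = NodeAttributes()
    desc = ""
    m = re.search(r"\[(.*)\]\s*$", text)
    if m:
        desc = m.group(1).strip()
        text = text[: m.start()].strip()
    m = re.search(r"\{(.*)\}\s*$", text)
    if m:
        for token in m.group(1).split(","):
            token = token.strip()
            if not token:
                continue
            if "=" in token:
                key, value = (part.strip() for part in token.split("=", 1))
            else:
                key, value = token, "true"
            if key in _FLAG_ATTRS:
                setattr(attrs, _FLAG_ATTRS[key], value.lower() == "true")
            elif key == "position":
                attrs.position = int(value)
            elif key == "type":
                attrs.type = value
            elif key == "unitClass":
                attrs.unit_class = value
            elif key == "predicateType":
                if value not in ("subclass", "property"):
                    raise SchemaError(f"bad predicateType {value!r}", line=lineno)
                attrs.predicate_type = value
            else:
                attrs.extras[key] = value
        text = text[: m.start()].strip()
    name = re.sub(r"\s+", " ", text)
    if not name:
        raise SchemaError("item without a name", line=lineno)
    return name, attrs, desc


def serialize_schema_wiki(schema: HedSchema) -> str:
    """Serialize to the MediaWiki dialect; re-parsing yields an equal schema."""
    out = io.StringIO()
    if schema.version:
        out.write(f'HED version="{schema.version}"\n\n')

    def markers(attrs: NodeAttributes) -> str:
        parts: List[str] = []
        for xml_name, py_name in _FLAG_ATTRS.items():
            if getattr(attrs, py_name):
                parts.append(xml_name)
        if attrs.position is not None:
            parts.append(f"position={attrs.position}")
        if attrs.type is not None:
            parts.append(f"type={attrs.type}")
        if attrs.unit_class is not None:
            parts.append(f"unitClass={attrs.unit_class}")
        if attrs.predicate_type != "subclass":
            parts.append(f"predicateType={attrs.predicate_type}")
        for key in sorted(attrs.extras):
            parts.append(f"{key}={attrs.extras[key]}")
        return " {" + ", ".join(parts) + "}" if parts else ""

    def write_node(node: SchemaNode, depth: int) -> None:
        suffix = markers(node.attributes)
        if node.description:
            suffix += f" [{node.description}]"
        if depth == 1:
            out.write(f"'''{node.name}'''{suffix}\n")
        else:
            out.write(f"{'*' * (depth - 1)} {node.name}{suffix}\n")
        for child in node.children:
            write_node(child, depth + 1)

    for root in schema.roots:
        write_node(root, 1)
        out.write("\n")
    if schema.unit_classes:
        out.write(f"{_WIKI_UNIT_SECTION}\n")
        for uc in schema.unit_classes.values():
            out.write(
                f"* {uc.name} {{default={uc.default_unit}}} "
                f"[{', '.join(uc.allowed_units)}]\n"
            )
    return out.getvalue()
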