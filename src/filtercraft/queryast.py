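"""Dialect-neutral query AST: term leaves, Boolean nodes, proximity nodes.

The same tree represents PubMed-dialect and Ovid-dialect (Medline/Embase)
filters; `dialect` on the enclosing Query controls which fields are legal and
how `to_string` renders the tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

DIALECTS = ("pubmed", "ovid_medline", "ovid_embase")

TEXT_FIELDS = ("tw", "tiab", "ti", "mp", "ec", "jn")
PUBMED_TEXT_FIELDS = ("tw", "tiab", "ti", "jn")
OVID_TEXT_FIELDS = ("mp", "tw", "ti", "ec")


@dataclass(frozen=True)
class TermLeaf:
    """One atomic search term.

    kind="text": `surface` is a (possibly multi-word) phrase; `truncated`
    means the final token is a stem (PubMed `*`, Ovid `$`); `wildcard` means
    the surface embeds `?` (matches 0 or 1 character).

    kind="descriptor": `surface` is a controlled-vocabulary heading;
    `explode` includes descendant headings, `major` requires the heading to
    be a major topic, `subheading` (optional) must qualify the heading.
    """

    kind: str
    surface: str
    field: str | None = None
    truncated: bool = False
    wildcard: bool = False
    explode: bool = False
    major: bool = False
    subheading: str | None = None

    def __post_init__(self):
        if self.kind not in ("text", "descriptor"):
            raise ValueError(f"bad leaf kind {self.kind!r}")
        if not self.surface:
            raise ValueError("empty term surface")
        if self.kind == "text" and (self.explode or self.major or self.subheading):
            raise ValueError("explode/major/subheading are descriptor-only")
        if self.kind == "descriptor" and (self.truncated or self.wildcard):
            raise ValueError("truncated/wildcard are text-only")


@dataclass(frozen=True)
class ProximityNode:
    """Ovid adjacency: left and right are a TermLeaf or an OR of TermLeaves.

    distance=1 with ordered=True is bare `adj` (left immediately before
    right); `adjN` (N>=2) means within N tokens, either order.
    """

    left: object
    right: object
    distance: int = 1
    field: str | None = None
    ordered: bool = True

    def __post_init__(self):
        if self.distance < 1:
            raise ValueError(f"proximity distance must be >= 1, got {self.distance}")
        for side in (self.left, self.right):
            if not _is_leaf_or_or_of_leaves(side):
                raise ValueError(
                    "proximity operands must be a term or an OR of terms"
                )


def _is_leaf_or_or_of_leaves(node) -> bool:
    if isinstance(node, TermLeaf):
        return node.kind == "text"
    if isinstance(node, BooleanNode) and node.op == "OR":
        return all(isinstance(c, TermLeaf) and c.kind == "text" for c in node.children)
    return False


@dataclass(frozen=True)
class BooleanNode:
    op: str  # AND | OR | NOT
    children: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "children", tuple(self.children))
        if self.op not in ("AND", "OR", "NOT"):
            raise ValueError(f"bad Boolean op {self.op!r}")
        if self.op == "NOT":
            if len(self.children) != 2:
                raise ValueError("NOT is binary: A NOT B")
        elif len(self.children) < 2:
            raise ValueError(f"{self.op} needs >= 2 children")
        if any(c is None for c in self.children):
            raise ValueError("empty child in Boolean node")


@dataclass(frozen=True)
class Query:
    root: object
    dialect: str
    source_text: str = ""

    def __post_init__(self):
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.root is None:
            raise ValueError("empty query")
        legal = PUBMED_TEXT_FIELDS if self.dialect == "pubmed" else OVID_TEXT_FIELDS
        for leaf in iter_leaves(self.root):
            if isinstance(leaf, TermLeaf) and leaf.kind == "text":
                if leaf.field is not None and leaf.field not in legal:
                    raise ValueError(
                        f"field {leaf.field!r} is not legal in dialect {self.dialect}"
                    )

    def __eq__(self, other):
        # Structural (AST) equality; the original source text is incidental.
        if not isinstance(other, Query):
            return NotImplemented
        return self.dialect == other.dialect and self.root == other.root

    def __hash__(self):
        return hash((self.dialect, self.root))


def iter_leaves(node):
    """Yield every TermLeaf in the tree (proximity sides included)."""
    if isinstance(node, TermLeaf):
        yield node
    elif isinstance(node, ProximityNode):
        yield from iter_leaves(node.left)
        yield from iter_leaves(node.right)
    elif isinstance(node, BooleanNode):
        for c in node.children:
            yield from iter_leaves(c)
    elif isinstance(node, Query):
        yield from iter_leaves(node.root)
    else:
        raise TypeError(f"not a query node: {node!r}")


def count_leaves(query) -> int:
    """Number of atomic terms: every text/descriptor leaf counts one,
    including each alternative inside a proximity OR-group."""
    return sum(1 for _ in iter_leaves(query))


# ---------------------------------------------------------------------------
# Rendering


def to_string(query: Query) -> str:
    """Emit dialect-correct text; reparsing yields an AST-equal query."""
    if query.dialect == "pubmed":
        return _render_pubmed(query.root, top=True)
    return _render_ovid(query.root, top=True)


def _pubmed_tag(leaf: TermLeaf) -> str:
    if leaf.kind == "text":
        return leaf.field or "tw"
    tag = "majr" if leaf.major else "mh"
    if not leaf.explode:
        tag += ":noexp"
    return tag


def _render_pubmed(node, top=False) -> str:
    if isinstance(node, TermLeaf):
        if node.kind == "descriptor":
            name = node.surface
            if node.subheading:
                name = f"{name}/{node.subheading}"
            return f'"{name}"[{_pubmed_tag(node)}]'
        surface = node.surface + ("*" if node.truncated else "")
        return f"{surface}[{_pubmed_tag(node)}]"
    if isinstance(node, BooleanNode):
        if node.op == "NOT":
            a, b = node.children
            body = f"{_render_pubmed(a)} NOT {_render_pubmed(b)}"
        else:
            body = f" {node.op} ".join(_render_pubmed(c) for c in node.children)
        return body if top else f"({body})"
    raise TypeError(f"cannot render {node!r} in pubmed dialect")


_OVID_RESERVED = re.compile(r"(?i)\b(and|or|not|exp|adj\d*)\b|[./,()*\"]")


def _render_ovid_leaf_bare(leaf: TermLeaf) -> str:
    """Leaf surface without field suffix (for proximity operands)."""
    surface = leaf.surface + ("$" if leaf.truncated else "")
    if _OVID_RESERVED.search(surface):
        return f'"{surface}"'
    return surface


def _render_ovid(node, top=False) -> str:
    if isinstance(node, TermLeaf):
        if node.kind == "descriptor":
            prefix = ("exp " if node.explode else "") + ("*" if node.major else "")
            name = node.surface
            if node.subheading:
                name = f"{name}/{node.subheading}"
                return f"{prefix}{name}"
            return f"{prefix}{name}/"
        surface = _render_ovid_leaf_bare(node)
        return f"{surface}.{node.field or 'mp'}"
    if isinstance(node, ProximityNode):
        op = "adj" if (node.distance == 1 and node.ordered) else f"adj{node.distance}"
        left = _render_prox_side(node.left)
        right = _render_prox_side(node.right)
        body = f"({left} {op} {right})"
        return f"{body}.{node.field or 'mp'}"
    if isinstance(node, BooleanNode):
        if node.op == "NOT":
            a, b = node.children
            body = f"{_render_ovid(a)} NOT {_render_ovid(b)}"
        else:
            body = f" {node.op} ".join(_render_ovid(c) for c in node.children)
        return body if top else f"({body})"
    raise TypeError(f"cannot render {node!r} in ovid dialect")


def _render_prox_side(side) -> str:
    if isinstance(side, TermLeaf):
        return _render_ovid_leaf_bare(side)
    body = " or ".join(_render_ovid_leaf_bare(c) for c in side.children)
    return f"({body})"
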