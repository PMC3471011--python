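"""Recursive-descent parsers for PubMed-dialect and Ovid-dialect queries.

PubMed dialect: `term[tag]` atoms with tags [tw] [tiab] [ti] [jn] [mh]
[mh:noexp] [majr] [majr:noexp], `*` truncation, quoted phrases, AND/OR/NOT.

Ovid dialect (Medline and Embase): descriptor atoms `Name/`, `exp Name/`,
`*Name/`, `exp *Name/`; text atoms with suffix fields .mp .tw .ti .ec (a
bare term defaults to .mp); `$` truncation; `?` zero-or-one-character
wildcard; `adj`/`adjN` proximity whose operands are terms or parenthesized
OR-groups of terms; a suffix after a parenthesized group distributes to the
unfielded terms inside it.

Operator precedence in both dialects: OR < AND < NOT < adj; all printed
filters are fully parenthesized, so precedence rarely matters in practice.
"""

from __future__ import annotations

import dataclasses
import re

from .queryast import BooleanNode, ProximityNode, Query, TermLeaf


class ParseError(ValueError):
    def __init__(self, message: str, text: str, pos: int):
        self.pos = pos
        super().__init__(f"{message} (at position {pos}: ...{text[pos:pos + 20]!r})")


_PUBMED_TAGS = {
    "tw": ("text", "tw"),
    "tiab": ("text", "tiab"),
    "ti": ("text", "ti"),
    "jn": ("text", "jn"),
    "mh": ("descriptor", None),
    "majr": ("descriptor", None),
}

_OVID_SUFFIXES = {"mp", "tw", "ti", "ec", "jn"}

_OPS = {"and": "AND", "or": "OR", "not": "NOT"}


# ---------------------------------------------------------------------------
# Tokenizers


class _Tok:
    __slots__ = ("kind", "value", "pos")

    def __init__(self, kind, value, pos):
        self.kind = kind
        self.value = value
        self.pos = pos

    def __repr__(self):
        return f"_Tok({self.kind},{self.value!r}@{self.pos})"


_PUBMED_WORD = re.compile(r'[^\s()\[\]"]+')
_PUBMED_TAG = re.compile(r"\[\s*([A-Za-z]+)(?:\s*:\s*noexp)?\s*\]")
_OVID_WORD = re.compile(r'[^\s()./,*"]+')
_OVID_SUFFIX = re.compile(r"\.\s*([A-Za-z]{2})\b\.?")
_ADJ = re.compile(r"adj(\d*)$", re.IGNORECASE)


def _lex_pubmed(text: str) -> list[_Tok]:
    toks, i, n = [], 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch == "(":
            toks.append(_Tok("LP", ch, i)); i += 1
        elif ch == ")":
            toks.append(_Tok("RP", ch, i)); i += 1
        elif ch == '"':
            j = text.find('"', i + 1)
            if j < 0:
                raise ParseError("unterminated quote", text, i)
            toks.append(_Tok("QUOTED", text[i + 1:j], i))
            i = j + 1
        elif ch == "[":
            m = _PUBMED_TAG.match(text, i)
            if not m:
                raise ParseError("malformed field tag", text, i)
            tag = m.group(1).lower()
            noexp = "noexp" in m.group(0).lower()
            if tag not in _PUBMED_TAGS:
                raise ParseError(f"unknown field tag [{tag}]", text, i)
            toks.append(_Tok("TAG", (tag, noexp), i))
            i = m.end()
        else:
            m = _PUBMED_WORD.match(text, i)
            if not m:
                raise ParseError(f"unexpected character {ch!r}", text, i)
            word = m.group(0)
            op = _OPS.get(word.lower())
            toks.append(_Tok("OP", op, i) if op else _Tok("WORD", word, i))
            i = m.end()
    return toks


def _lex_ovid(text: str) -> list[_Tok]:
    toks, i, n = [], 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch == "(":
            toks.append(_Tok("LP", ch, i)); i += 1
        elif ch == ")":
            toks.append(_Tok("RP", ch, i)); i += 1
        elif ch == "/":
            toks.append(_Tok("SLASH", ch, i)); i += 1
        elif ch == ",":
            toks.append(_Tok("COMMA", ch, i)); i += 1
        elif ch == "*":
            toks.append(_Tok("STAR", ch, i)); i += 1
        elif ch == '"':
            j = text.find('"', i + 1)
            if j < 0:
                raise ParseError("unterminated quote", text, i)
            toks.append(_Tok("QUOTED", text[i + 1:j], i))
            i = j + 1
        elif ch == ".":
            m = _OVID_SUFFIX.match(text, i)
            if not m or m.group(1).lower() not in _OVID_SUFFIXES:
                raise ParseError("unknown field suffix", text, i)
            toks.append(_Tok("SUFFIX", m.group(1).lower(), i))
            i = m.end()
        else:
            m = _OVID_WORD.match(text, i)
            if not m:
                raise ParseError(f"unexpected character {ch!r}", text, i)
            word = m.group(0)
            low = word.lower()
            if low in _OPS:
                toks.append(_Tok("OP", _OPS[low], i))
            elif low == "exp":
                toks.append(_Tok("EXP", word, i))
            elif _ADJ.match(low):
                dist = _ADJ.match(low).group(1)
                if dist == "0":
                    raise ParseError("adj0 is not a valid proximity operator", text, i)
                toks.append(_Tok("ADJ", int(dist) if dist else 1, i))
            else:
                toks.append(_Tok("WORD", word, i))
            i = m.end()
    return toks


# ---------------------------------------------------------------------------
# Shared parser machinery


class _Parser:
    def __init__(self, toks, text):
        self.toks = toks
        self.text = text
        self.i = 0

    def peek(self, *kinds):
        if self.i < len(self.toks) and self.toks[self.i].kind in kinds:
            return self.toks[self.i]
        return None

    def next(self):
        tok = self.toks[self.i]
        self.i += 1
        return tok

    def expect(self, kind, what):
        tok = self.peek(kind)
        if tok is None:
            pos = self.toks[self.i].pos if self.i < len(self.toks) else len(self.text)
            raise ParseError(f"expected {what}", self.text, pos)
        return self.next()

    def error(self, msg):
        pos = self.toks[self.i].pos if self.i < len(self.toks) else len(self.text)
        raise ParseError(msg, self.text, pos)

    # precedence: OR < AND < NOT
    def parse_expr(self):
        node = self.parse_and()
        children = [node]
        while (t := self.peek("OP")) and t.value == "OR":
            self.next()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else BooleanNode("OR", children)

    def parse_and(self):
        node = self.parse_not()
        children = [node]
        while (t := self.peek("OP")) and t.value == "AND":
            self.next()
            children.append(self.parse_not())
        return children[0] if len(children) == 1 else BooleanNode("AND", children)

    def parse_not(self):
        node = self.parse_prox()
        while (t := self.peek("OP")) and t.value == "NOT":
            self.next()
            node = BooleanNode("NOT", (node, self.parse_prox()))
        return node

    def parse_prox(self):  # overridden for Ovid
        return self.parse_atom()

    def parse_atom(self):
        raise NotImplementedError


# ---------------------------------------------------------------------------
# PubMed


class _PubmedParser(_Parser):
    def parse_atom(self):
        if self.peek("LP"):
            self.next()
            node = self.parse_expr()
            self.expect("RP", "')'")
            return node
        return self.parse_term()

    def parse_term(self):
        if (q := self.peek("QUOTED")) is not None:
            self.next()
            phrase = q.value
        else:
            words = []
            while self.peek("WORD"):
                words.append(self.next().value)
            if not words:
                self.error("expected a search term")
            phrase = " ".join(words)
        tag, noexp = ("tw", False)
        if self.peek("TAG"):
            tag, noexp = self.next().value
        kind, field = _PUBMED_TAGS[tag]
        if kind == "descriptor":
            name, subheading = phrase, None
            if "/" in phrase:
                name, _, subheading = phrase.partition("/")
            return TermLeaf(
                kind="descriptor",
                surface=name.strip(),
                field="mh",
                explode=not noexp,
                major=tag == "majr",
                subheading=subheading.strip() if subheading else None,
            )
        truncated = phrase.endswith("*")
        surface = phrase.rstrip("*")
        if not surface:
            self.error("empty term")
        return TermLeaf(
            kind="text",
            surface=surface,
            field=field,
            truncated=truncated,
            wildcard="?" in surface,
        )


def parse_pubmed(text: str) -> Query:
    if not text or not text.strip():
        raise ParseError("empty query", text or "", 0)
    p = _PubmedParser(_lex_pubmed(text), text)
    root = p.parse_expr()
    if p.i != len(p.toks):
        p.error("unexpected trailing input (unbalanced parentheses?)")
    return Query(root=root, dialect="pubmed", source_text=text)


# ---------------------------------------------------------------------------
# Ovid


class _OvidParser(_Parser):
    def parse_prox(self):
        node = self.parse_atom()
        while self.peek("ADJ"):
            tok = self.next()
            right = self.parse_atom()
            dist = tok.value
            try:
                node = ProximityNode(
                    left=node,
                    right=right,
                    distance=dist,
                    ordered=dist == 1,
                    field=None,
                )
            except ValueError as exc:
                raise ParseError(str(exc), self.text, tok.pos) from None
            # a suffix directly after the proximity group, e.g. (a adj b).mp
            if self.peek("SUFFIX"):
                node = dataclasses.replace(node, field=self.next().value)
        return node

    def parse_atom(self):
        if self.peek("LP"):
            self.next()
            node = self.parse_expr()
            self.expect("RP", "')'")
            if self.peek("SUFFIX"):
                node = _distribute_field(node, self.next().value)
            return node
        return self.parse_term()

    def parse_term(self):
        explode = False
        major = False
        if self.peek("EXP"):
            self.next()
            explode = True
        if self.peek("STAR"):
            self.next()
            major = True
        if (q := self.peek("QUOTED")) is not None:
            self.next()
            phrase = q.value
        else:
            parts = []
            while True:
                if self.peek("WORD"):
                    parts.append(self.next().value)
                elif self.peek("COMMA"):
                    self.next()
                    if parts:
                        parts[-1] += ","
                else:
                    break
            if not parts:
                self.error("expected a search term")
            phrase = " ".join(parts)
        if self.peek("SLASH"):
            self.next()
            return TermLeaf(
                kind="descriptor",
                surface=phrase,
                field="mh",
                explode=explode,
                major=major,
            )
        if explode or major:
            self.error(f"descriptor syntax requires a trailing '/': {phrase!r}")
        field = None
        if self.peek("SUFFIX"):
            field = self.next().value
        truncated = phrase.endswith("$") or phrase.endswith("*")
        surface = phrase.rstrip("$*")
        if not surface:
            self.error("empty term")
        return TermLeaf(
            kind="text",
            surface=surface,
            field=field,
            truncated=truncated,
            wildcard="?" in surface,
        )


def _distribute_field(node, field: str):
    """Apply a group suffix field to every unfielded text atom inside."""
    if isinstance(node, TermLeaf):
        if node.kind == "text" and node.field is None:
            return dataclasses.replace(node, field=field)
        return node
    if isinstance(node, ProximityNode):
        if node.field is None:
            return dataclasses.replace(node, field=field)
        return node
    if isinstance(node, BooleanNode):
        return BooleanNode(node.op, tuple(_distribute_field(c, field) for c in node.children))
    return node


def _finalize_ovid_defaults(node):
    """Remaining unfielded text atoms default to .mp (proximity operands keep
    no field of their own: the field lives on the proximity node)."""
    if isinstance(node, TermLeaf):
        if node.kind == "text" and node.field is None:
            return dataclasses.replace(node, field="mp")
        return node
    if isinstance(node, ProximityNode):
        if node.field is None:
            return dataclasses.replace(node, field="mp")
        return node
    if isinstance(node, BooleanNode):
        return BooleanNode(node.op, tuple(_finalize_ovid_defaults(c) for c in node.children))
    return node


def parse_ovid(text: str, dialect: str = "ovid_medline") -> Query:
    if dialect not in ("ovid_medline", "ovid_embase"):
        raise ValueError(f"not an Ovid dialect: {dialect!r}")
    if not text or not text.strip():
        raise ParseError("empty query", text or "", 0)
    p = _OvidParser(_lex_ovid(text), text)
    root = p.parse_expr()
    if p.i != len(p.toks):
        p.error("unexpected trailing input (unbalanced parentheses?)")
    root = _finalize_ovid_defaults(root)
    return Query(root=root, dialect=dialect, source_text=text)


def parse(text: str, dialect: str) -> Query:
    """Parse ``text`` in the named dialect (pubmed | ovid_medline | ovid_embase)."""
    if dialect == "pubmed":
        return parse_pubmed(text)
    return parse_ovid(text, dialect)
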