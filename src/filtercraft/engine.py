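"""Evaluate parsed queries against citation records.

Field semantics (mirroring how the bibliographic databases search):

- ``ti``          title tokens only
- ``tiab``        title + abstract tokens
- ``tw`` / ``mp`` title + abstract, plus the indexing-derived text of the
                  record: descriptor names, subheadings, and entry-term
                  strings, each rendered as its own token sequence
- ``ec``          exact (case-insensitive) match on classification codes
- ``jn``          exact match on the journal identifier — and the journal
                  name satisfies *only* this field: a term occurring solely
                  in the journal name never matches a text field

Descriptor leaves match against the record's index terms after resolving
names through the thesaurus: the leaf's target set is the descriptor itself
or, when exploded, all tree descendants; a major-topic leaf additionally
requires the index term's major flag; a subheading-qualified leaf requires
that subheading on the index term.

Tokenization: lowercase, hyphens split ("anti-glomerular" is the two-token
phrase [anti, glomerular]), other punctuation stripped.  Phrases match
consecutive tokens; truncation is a prefix match on the final token; ``?``
matches zero or one character at its position.
"""

from __future__ import annotations

import re
from functools import lru_cache

from .queryast import BooleanNode, ProximityNode, Query, TermLeaf

_WORD_RE = re.compile(r"[a-z0-9]+")
_QWORD_RE = re.compile(r"[a-z0-9?]+")


def tokenize(text: str) -> list[str]:
    """Record-text tokenizer: lowercase, hyphen-split, punctuation stripped."""
    return _WORD_RE.findall(text.lower().replace("-", " "))


def tokenize_query_phrase(text: str) -> list[str]:
    """Query-phrase tokenizer: like `tokenize` but keeps `?` wildcards."""
    return _QWORD_RE.findall(text.lower().replace("-", " "))


@lru_cache(maxsize=4096)
def _compile_phrase(surface: str, truncated: bool):
    """Compile a phrase into per-token matcher callables."""
    toks = tokenize_query_phrase(surface)
    if not toks:
        raise ValueError(f"term {surface!r} contains no searchable tokens")
    matchers = []
    for pos, tok in enumerate(toks):
        is_last = pos == len(toks) - 1
        prefix = truncated and is_last
        if "?" in tok:
            pattern = "".join(
                ".?" if c == "?" else re.escape(c) for c in tok
            )
            if prefix:
                pattern += ".*"
            rx = re.compile(f"^{pattern}$")
            matchers.append(rx.match)
        elif prefix:
            matchers.append(lambda s, _t=tok: s.startswith(_t))
        else:
            matchers.append(lambda s, _t=tok: s == _t)
    return tuple(matchers)


def _phrase_occurrences(matchers, seq) -> list[tuple[int, int]]:
    k = len(matchers)
    out = []
    for i in range(len(seq) - k + 1):
        if all(m(seq[i + j]) for j, m in enumerate(matchers)):
            out.append((i, i + k))
    return out


def _normalize_exact(s: str) -> str:
    return " ".join(s.strip().strip('"').split()).lower()


class RecordView:
    """Per-record token sequences, computed once and reused across queries."""

    __slots__ = (
        "record", "title", "abstract", "index_seqs", "codes", "journal",
    )

    def __init__(self, record):
        self.record = record
        self.title = tokenize(record.title)
        self.abstract = tokenize(record.abstract)
        seqs = []
        for term in record.index_terms:
            seqs.append(tokenize(term.descriptor_name))
            for sh in term.subheadings:
                seqs.append(tokenize(sh))
        for et in record.entry_term_strings:
            seqs.append(tokenize(et))
        self.index_seqs = seqs
        self.codes = frozenset(_normalize_exact(c) for c in record.classification_codes)
        self.journal = _normalize_exact(record.journal_id)

    def sequences(self, field: str):
        if field == "ti":
            return (self.title,)
        if field == "tiab":
            return (self.title, self.abstract)
        if field in ("tw", "mp"):
            return (self.title, self.abstract, *self.index_seqs)
        raise ValueError(f"field {field!r} has no token sequences")


def _eval_text_leaf(leaf: TermLeaf, view: RecordView) -> bool:
    field = leaf.field or "tw"
    if field == "ec":
        return _normalize_exact(leaf.surface) in view.codes
    if field == "jn":
        return _normalize_exact(leaf.surface) == view.journal
    matchers = _compile_phrase(leaf.surface, leaf.truncated)
    k = len(matchers)
    for seq in view.sequences(field):
        if len(seq) < k:
            continue
        for i in range(len(seq) - k + 1):
            if all(m(seq[i + j]) for j, m in enumerate(matchers)):
                return True
    return False


def _eval_descriptor_leaf(leaf: TermLeaf, view: RecordView, thesaurus) -> bool:
    if thesaurus is None:
        raise ValueError(f"descriptor term {leaf.surface!r} requires a thesaurus")
    target_desc = thesaurus.lookup(leaf.surface)  # KeyError if unresolvable
    if leaf.explode:
        targets = thesaurus.descendants(target_desc.name)
    else:
        targets = {target_desc.name}
    for term in view.record.index_terms:
        try:
            canonical = thesaurus.lookup(term.descriptor_name).name
        except KeyError:
            continue  # junk indexing never matches, but is not an error
        if canonical not in targets:
            continue
        if leaf.major and not term.major:
            continue
        if leaf.subheading is not None:
            subs = {s.lower() for s in term.subheadings}
            if leaf.subheading.lower() not in subs:
                continue
        return True
    return False


def _side_occurrences(side, seq) -> list[tuple[int, int]]:
    if isinstance(side, TermLeaf):
        return _phrase_occurrences(_compile_phrase(side.surface, side.truncated), seq)
    out = []
    for alt in side.children:
        out.extend(
            _phrase_occurrences(_compile_phrase(alt.surface, alt.truncated), seq)
        )
    return out


def _eval_proximity(node: ProximityNode, view: RecordView) -> bool:
    field = node.field or "mp"
    for seq in view.sequences(field):
        left_occ = _side_occurrences(node.left, seq)
        if not left_occ:
            continue
        right_occ = _side_occurrences(node.right, seq)
        if not right_occ:
            continue
        for (li, lj) in left_occ:
            for (ri, rj) in right_occ:
                if node.ordered:
                    # left must directly precede right within the gap
                    if ri >= lj and ri - lj <= node.distance - 1:
                        return True
                else:
                    if ri >= lj and ri - lj <= node.distance - 1:
                        return True
                    if li >= rj and li - rj <= node.distance - 1:
                        return True
    return False


def _eval(node, view: RecordView, thesaurus) -> bool:
    if isinstance(node, TermLeaf):
        if node.kind == "descriptor":
            return _eval_descriptor_leaf(node, view, thesaurus)
        return _eval_text_leaf(node, view)
    if isinstance(node, ProximityNode):
        return _eval_proximity(node, view)
    if isinstance(node, BooleanNode):
        if node.op == "OR":
            return any(_eval(c, view, thesaurus) for c in node.children)
        if node.op == "AND":
            return all(_eval(c, view, thesaurus) for c in node.children)
        a, b = node.children
        return _eval(a, view, thesaurus) and not _eval(b, view, thesaurus)
    raise TypeError(f"not a query node: {node!r}")


def matches(query, record, thesaurus=None) -> bool:
    """Does ``record`` satisfy ``query``?  ``query`` may be a Query or a bare
    AST node."""
    root = query.root if isinstance(query, Query) else query
    return _eval(root, RecordView(record), thesaurus)


def _corpus_views(corpus) -> list[RecordView]:
    views = getattr(corpus, "_token_views", None)
    if views is None:
        views = [RecordView(r) for r in corpus.records]
        try:
            corpus._token_views = views
        except AttributeError:
            pass
    return views


def retrieve(query, corpus, thesaurus=None) -> set[str]:
    """The set of uids in ``corpus`` matching ``query``."""
    root = query.root if isinstance(query, Query) else query
    return {
        v.record.uid for v in _corpus_views(corpus) if _eval(root, v, thesaurus)
    }
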