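"""Independent reference implementations used only by the test suite.

Everything here re-derives results by the most literal method available —
brute-force prefix scans, per-leaf set materialization followed by set
algebra, exhaustive enumeration — deliberately avoiding the package's
evaluator internals so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import re
import string
from functools import lru_cache

from filtercraft.corpus import CitationRecord, IndexTerm, LabeledCorpus
from filtercraft.queryast import BooleanNode, ProximityNode, Query, TermLeaf

# ---------------------------------------------------------------------------
# Tokenization (same definition as the spec'd semantics, different code)

_PUNCT = "".join(c for c in string.punctuation if c not in "-")
_TABLE = str.maketrans({c: " " for c in _PUNCT + "-"})


@lru_cache(maxsize=None)
def toks(text: str) -> tuple[str, ...]:
    return tuple(text.lower().translate(_TABLE).split())


@lru_cache(maxsize=None)
def _qtoks(text: str) -> tuple[str, ...]:
    table = str.maketrans({c: " " for c in (_PUNCT.replace("?", "") + "-")})
    return tuple(text.lower().translate(table).split())


@lru_cache(maxsize=None)
def _token_rx(pattern: str, prefix: bool):
    rx = "".join(".?" if c == "?" else re.escape(c) for c in pattern)
    if prefix:
        rx += ".*"
    return re.compile(rx)


def _token_matches(pattern: str, token: str, prefix: bool) -> bool:
    return _token_rx(pattern, prefix).fullmatch(token) is not None


def phrase_positions(surface: str, truncated: bool, seq: list[str]):
    """All (start, end) occurrences of the phrase in the token sequence."""
    pts = _qtoks(surface)
    out = []
    for i in range(len(seq) - len(pts) + 1):
        ok = True
        for j, pt in enumerate(pts):
            prefix = truncated and j == len(pts) - 1
            if not _token_matches(pt, seq[i + j], prefix):
                ok = False
                break
        if ok:
            out.append((i, i + len(pts)))
    return out


# ---------------------------------------------------------------------------
# Naive per-record evaluation: materialize leaf sets, then set algebra


def _norm(s: str) -> str:
    return " ".join(s.strip().strip('"').split()).lower()


def _record_sequences(rec: CitationRecord, field: str):
    if field == "ti":
        return [toks(rec.title)]
    if field == "tiab":
        return [toks(rec.title), toks(rec.abstract)]
    seqs = [toks(rec.title), toks(rec.abstract)]
    for t in rec.index_terms:
        seqs.append(toks(t.descriptor_name))
        seqs.extend(toks(s) for s in t.subheadings)
    seqs.extend(toks(e) for e in rec.entry_term_strings)
    return seqs


def leaf_matches_record(leaf: TermLeaf, rec: CitationRecord, thesaurus) -> bool:
    if leaf.kind == "descriptor":
        target = thesaurus.lookup(leaf.surface).name
        targets = (
            descendants_bruteforce(thesaurus, target) if leaf.explode else {target}
        )
        for t in rec.index_terms:
            try:
                canon = thesaurus.lookup(t.descriptor_name).name
            except KeyError:
                continue
            if canon in targets and (t.major or not leaf.major):
                if leaf.subheading is None or leaf.subheading.lower() in {
                    s.lower() for s in t.subheadings
                }:
                    return True
        return False
    field = leaf.field or "tw"
    if field == "ec":
        return _norm(leaf.surface) in {_norm(c) for c in rec.classification_codes}
    if field == "jn":
        return _norm(leaf.surface) == _norm(rec.journal_id)
    return any(
        phrase_positions(leaf.surface, leaf.truncated, seq)
        for seq in _record_sequences(rec, field)
    )


def prox_matches_record(node: ProximityNode, rec: CitationRecord) -> bool:
    def side_pos(side, seq):
        leaves = [side] if isinstance(side, TermLeaf) else list(side.children)
        pos = []
        for lf in leaves:
            pos.extend(phrase_positions(lf.surface, lf.truncated, seq))
        return pos

    for seq in _record_sequences(rec, node.field or "mp"):
        for (li, lj), (ri, rj) in itertools.product(
            side_pos(node.left, seq), side_pos(node.right, seq)
        ):
            if node.ordered:
                if ri >= lj and ri - lj <= node.distance - 1:
                    return True
            else:
                gap = ri - lj if ri >= lj else li - rj
                if (ri >= lj or li >= rj) and gap <= node.distance - 1:
                    return True
    return False


def naive_retrieve(query, corpus: LabeledCorpus, thesaurus=None) -> set[str]:
    """Materialize a uid set per leaf/proximity atom, then apply set algebra."""
    node = query.root if isinstance(query, Query) else query

    def atom_set(n) -> set[str]:
        if isinstance(n, TermLeaf):
            return {
                r.uid for r in corpus if leaf_matches_record(n, r, thesaurus)
            }
        return {r.uid for r in corpus if prox_matches_record(n, r)}

    def ev(n) -> set[str]:
        if isinstance(n, (TermLeaf, ProximityNode)):
            return atom_set(n)
        if n.op == "OR":
            out = set()
            for c in n.children:
                out |= ev(c)
            return out
        if n.op == "AND":
            parts = [ev(c) for c in n.children]
            out = parts[0]
            for p in parts[1:]:
                out &= p
            return out
        a, b = n.children
        return ev(a) - ev(b)

    return ev(node)


# ---------------------------------------------------------------------------
# Thesaurus oracle


def descendants_bruteforce(thesaurus, name: str) -> set[str]:
    d = thesaurus.lookup(name)
    out = {d.name}
    for other in thesaurus.descriptors.values():
        for tn_query in d.tree_numbers:
            for tn in other.tree_numbers:
                if tn != tn_query and tn.startswith(tn_query + "."):
                    out.add(other.name)
    return out


# ---------------------------------------------------------------------------
# Random corpora and queries


def random_corpus(rng, n_records=60, n_journals=5, vocab=None, thesaurus=None,
                  labeled=True) -> LabeledCorpus:
    vocab = vocab or [
        "kidney", "renal", "glomerulonephritis", "proteinuria", "biopsy",
        "diabetic", "nephrotic", "lupus", "vasculitis", "chronic", "disease",
        "outcome", "therapy", "trial", "cohort", "anti", "membranous",
    ]
    desc_names = list(thesaurus.descriptors) if thesaurus is not None else []
    records, labels = [], {}
    for i in range(n_records):
        title = " ".join(rng.choice(vocab) for _ in range(rng.randint(3, 8)))
        abstract = " ".join(rng.choice(vocab) for _ in range(rng.randint(0, 25)))
        terms = []
        if desc_names and rng.random() < 0.7:
            for name in rng.sample(desc_names, rng.randint(1, 3)):
                terms.append(
                    IndexTerm(
                        descriptor_name=name,
                        major=rng.random() < 0.3,
                        subheadings=("therapy",) if rng.random() < 0.3 else (),
                    )
                )
        uid = f"u{i:04d}"
        records.append(
            CitationRecord(
                uid=uid,
                journal_id=f"J{rng.randint(0, n_journals - 1)}",
                pub_year=2004 + i % 5,
                title=title,
                abstract=abstract,
                index_terms=tuple(terms),
                entry_term_strings=(rng.choice(vocab),) if rng.random() < 0.2 else (),
            )
        )
        labels[uid] = rng.random() < 0.3
    return LabeledCorpus(records, labels if labeled else None)


def random_query(rng, vocab, thesaurus=None, dialect="pubmed", max_depth=3):
    """A random AND/OR/NOT tree over text (and occasionally descriptor) leaves."""

    def leaf():
        if thesaurus is not None and rng.random() < 0.25:
            name = rng.choice(list(thesaurus.descriptors))
            return TermLeaf(
                kind="descriptor", surface=name, field="mh",
                explode=rng.random() < 0.5, major=rng.random() < 0.3,
            )
        word = rng.choice(vocab)
        truncated = rng.random() < 0.3
        if truncated and len(word) > 4:
            word = word[: rng.randint(3, len(word) - 1)]
        fields = ("tw", "tiab", "ti") if dialect == "pubmed" else ("mp", "tw", "ti")
        return TermLeaf(
            kind="text", surface=word, field=rng.choice(fields), truncated=truncated
        )

    def node(depth):
        if depth >= max_depth or rng.random() < 0.4:
            return leaf()
        op = rng.choice(["AND", "OR", "OR", "NOT"])
        if op == "NOT":
            return BooleanNode("NOT", (node(depth + 1), node(depth + 1)))
        return BooleanNode(
            op, tuple(node(depth + 1) for _ in range(rng.randint(2, 3)))
        )

    return Query(root=node(0), dialect=dialect)


# ---------------------------------------------------------------------------
# Exhaustive development oracle


def exhaustive_or_search(variant_uids, relevant, n_total, max_clauses,
                         objective="youden"):
    """Best objective value over every OR of <= max_clauses single variants."""
    n_rel = len(relevant)
    n_irr = n_total - n_rel
    best = None
    idx = range(len(variant_uids))
    for k in range(1, max_clauses + 1):
        for combo in itertools.combinations(idx, k):
            uids = set()
            for i in combo:
                uids |= variant_uids[i]
            a = len(uids & relevant)
            b = len(uids) - a
            sens = a / n_rel if n_rel else 0.0
            spec = 1 - (b / n_irr if n_irr else 0.0)
            value = sens + spec - 1 if objective == "youden" else None
            if best is None or value > best[0]:
                best = (value, combo, sens, spec)
    return best
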