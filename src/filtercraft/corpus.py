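"""Labeled citation corpora: data model, JSONL/.nbib I/O, journal-level splitting.

A corpus is the unit every other module works on: a set of bibliographic
records (title, abstract, index terms, classification codes, journal) plus an
optional consensus relevance label per record.  Filters are developed on one
journal-level slice of a corpus and validated on the other, mirroring the
development/validation design used in search-filter (hedge) studies.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

VALID_DATABASES = frozenset({"pubmed", "medline", "embase"})


@dataclass(frozen=True)
class IndexTerm:
    """A controlled-vocabulary heading attached to a record by indexing.

    ``major`` marks the heading as a major topic of the article (PubMed's
    starred headings).  ``subheadings`` qualify the heading ("therapy",
    "diagnosis", ...); the list may be empty.
    """

    descriptor_name: str
    major: bool = False
    subheadings: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.descriptor_name:
            raise ValueError("IndexTerm.descriptor_name must be non-empty")
        object.__setattr__(self, "subheadings", tuple(self.subheadings))
        if len(set(self.subheadings)) != len(self.subheadings):
            raise ValueError(
                f"duplicate subheadings on {self.descriptor_name!r}: "
                f"{list(self.subheadings)}"
            )


@dataclass(frozen=True)
class CitationRecord:
    """One bibliographic record as seen by a search interface."""

    uid: str
    journal_id: str
    pub_year: int
    title: str
    abstract: str = ""
    index_terms: tuple[IndexTerm, ...] = ()
    entry_term_strings: tuple[str, ...] = ()
    classification_codes: tuple[str, ...] = ()
    source_databases: frozenset[str] = frozenset({"pubmed"})

    def __post_init__(self):
        if not self.title:
            raise ValueError(f"record {self.uid!r}: title must be non-empty")
        if self.pub_year < 1800:
            raise ValueError(f"record {self.uid!r}: pub_year {self.pub_year} < 1800")
        object.__setattr__(self, "index_terms", tuple(self.index_terms))
        object.__setattr__(self, "entry_term_strings", tuple(self.entry_term_strings))
        object.__setattr__(
            self, "classification_codes", tuple(self.classification_codes)
        )
        dbs = frozenset(self.source_databases)
        unknown = dbs - VALID_DATABASES
        if unknown:
            raise ValueError(f"record {self.uid!r}: unknown databases {sorted(unknown)}")
        object.__setattr__(self, "source_databases", dbs)


@dataclass(frozen=True)
class RelevanceLabel:
    """One reader's relevance judgement for one record."""

    uid: str
    relevant: bool
    reader_id: str = ""


class LabeledCorpus:
    """Citation records plus (optionally) one consensus relevance label each.

    ``labels`` maps uid -> bool.  When labels are present every record must
    carry exactly one; an unlabeled corpus (``labels is None``) supports
    retrieval but not diagnostic evaluation.
    """

    def __init__(self, records, labels=None):
        records = list(records)
        seen = set()
        for r in records:
            if r.uid in seen:
                raise ValueError(f"duplicate uid {r.uid}")
            seen.add(r.uid)
        self.records = records
        self._by_uid = {r.uid: r for r in records}
        if labels is not None:
            labels = dict(labels)
            missing = seen - labels.keys()
            extra = labels.keys() - seen
            if extra:
                raise ValueError(f"labels for unknown uids: {sorted(extra)[:5]}")
            if missing:
                raise ValueError(
                    f"{len(missing)} records lack a consensus label "
                    f"(e.g. {sorted(missing)[:5]})"
                )
        self.labels = labels

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, uid: str) -> CitationRecord:
        return self._by_uid[uid]

    def __contains__(self, uid: str) -> bool:
        return uid in self._by_uid

    def __eq__(self, other):
        if not isinstance(other, LabeledCorpus):
            return NotImplemented
        return self.records == other.records and self.labels == other.labels

    @property
    def uids(self) -> set[str]:
        return set(self._by_uid)

    @property
    def journals(self) -> set[str]:
        return {r.journal_id for r in self.records}

    @property
    def relevant_uids(self) -> set[str]:
        self._require_labels()
        return {u for u, lab in self.labels.items() if lab}

    def _require_labels(self):
        if self.labels is None:
            raise ValueError("corpus has no relevance labels")

    def restrict_to_database(self, database: str) -> "LabeledCorpus":
        """Per-database view: the sub-corpus of records carried by ``database``."""
        if database not in VALID_DATABASES:
            raise ValueError(f"unknown database {database!r}")
        recs = [r for r in self.records if database in r.source_databases]
        labels = None
        if self.labels is not None:
            labels = {r.uid: self.labels[r.uid] for r in recs}
        return LabeledCorpus(recs, labels)

    def restrict_to_journals(self, journal_ids) -> "LabeledCorpus":
        journal_ids = set(journal_ids)
        recs = [r for r in self.records if r.journal_id in journal_ids]
        labels = None
        if self.labels is not None:
            labels = {r.uid: self.labels[r.uid] for r in recs}
        return LabeledCorpus(recs, labels)


@dataclass(frozen=True)
class JournalSplit:
    """A journal-level partition into development and validation sets."""

    development_journals: frozenset[str]
    validation_journals: frozenset[str]
    seed: int

    def __post_init__(self):
        overlap = self.development_journals & self.validation_journals
        if overlap:
            raise ValueError(f"journals on both sides: {sorted(overlap)}")


def consensus_from_labels(labels) -> dict[str, bool]:
    """Majority-vote consensus over per-reader labels; ties are an error.

    The original study used readers calibrated against an expert; no
    tie-breaking rule exists, so a tie is treated as an unresolved conflict.
    """
    votes: dict[str, list[bool]] = {}
    for lab in labels:
        votes.setdefault(lab.uid, []).append(lab.relevant)
    out = {}
    for uid, vs in votes.items():
        yes = sum(vs)
        no = len(vs) - yes
        if yes == no:
            raise ValueError(f"tied reader votes for uid {uid}")
        out[uid] = yes > no
    return out


# ---------------------------------------------------------------------------
# JSONL dialect


def _record_from_json(obj: dict) -> tuple[CitationRecord, bool | None]:
    terms = tuple(
        IndexTerm(
            descriptor_name=t["descriptor"],
            major=bool(t.get("major", False)),
            subheadings=tuple(t.get("subheadings", ())),
        )
        for t in obj.get("index_terms", ())
    )
    rec = CitationRecord(
        uid=obj["uid"],
        journal_id=obj["journal_id"],
        pub_year=int(obj["pub_year"]),
        title=obj["title"],
        abstract=obj.get("abstract", ""),
        index_terms=terms,
        entry_term_strings=tuple(obj.get("entry_term_strings", ())),
        classification_codes=tuple(obj.get("classification_codes", ())),
        source_databases=frozenset(obj.get("source_databases", ("pubmed",))),
    )
    return rec, obj.get("relevant")


def _record_to_json(rec: CitationRecord, relevant: bool | None) -> dict:
    obj = {
        "uid": rec.uid,
        "journal_id": rec.journal_id,
        "pub_year": rec.pub_year,
        "title": rec.title,
        "abstract": rec.abstract,
        "index_terms": [
            {
                "descriptor": t.descriptor_name,
                "major": t.major,
                "subheadings": list(t.subheadings),
            }
            for t in rec.index_terms
        ],
        "entry_term_strings": list(rec.entry_term_strings),
        "classification_codes": list(rec.classification_codes),
        "source_databases": sorted(rec.source_databases),
    }
    if relevant is not None:
        obj["relevant"] = bool(relevant)
    return obj


def load_jsonl(path) -> LabeledCorpus:
    records, labels = [], {}
    any_label = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                rec, relevant = _record_from_json(obj)
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: malformed record on line {lineno}: {exc}") from exc
            records.append(rec)
            if relevant is not None:
                any_label = True
                labels[rec.uid] = bool(relevant)
    return LabeledCorpus(records, labels if any_label else None)


def write_jsonl(corpus: LabeledCorpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus.records:
            relevant = corpus.labels.get(rec.uid) if corpus.labels is not None else None
            fh.write(json.dumps(_record_to_json(rec, relevant), sort_keys=True))
            fh.write("\n")


def corpus_to_jsonl_text(corpus: LabeledCorpus) -> str:
    buf = io.StringIO()
    for rec in corpus.records:
        relevant = corpus.labels.get(rec.uid) if corpus.labels is not None else None
        buf.write(json.dumps(_record_to_json(rec, relevant), sort_keys=True))
        buf.write("\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# MEDLINE .nbib subset

_NBIB_KNOWN_TAGS = {"PMID", "TA", "DP", "TI", "AB", "MH"}


def parse_mh_field(mh: str) -> IndexTerm:
    """Parse one MH value: `/` separates subheadings; a leading `*` anywhere
    marks the heading as major topic."""
    parts = mh.split("/")
    major = any(p.startswith("*") for p in parts)
    parts = [p.lstrip("*").strip() for p in parts]
    return IndexTerm(
        descriptor_name=parts[0],
        major=major,
        subheadings=tuple(p for p in parts[1:] if p),
    )


def load_nbib(path) -> LabeledCorpus:
    from Bio import Medline

    records = []
    warned: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for i, entry in enumerate(Medline.parse(fh), start=1):
            for tag in entry:
                if tag not in _NBIB_KNOWN_TAGS and tag not in warned:
                    warned.add(tag)
                    logger.warning("ignoring unknown .nbib tag %s", tag)
            try:
                uid = entry["PMID"]
                dp = entry.get("DP", "")
                year = int(dp[:4]) if dp[:4].isdigit() else 1900
                terms = tuple(parse_mh_field(mh) for mh in entry.get("MH", ()))
                records.append(
                    CitationRecord(
                        uid=uid,
                        journal_id=entry.get("TA", "unknown"),
                        pub_year=year,
                        title=entry.get("TI", "(untitled)") or "(untitled)",
                        abstract=entry.get("AB", ""),
                        index_terms=terms,
                        source_databases=frozenset({"pubmed", "medline"}),
                    )
                )
            except KeyError as exc:
                raise ValueError(f"{path}: record {i} missing field {exc}") from exc
    return LabeledCorpus(records, None)


def load_corpus(path, format: str = "jsonl") -> LabeledCorpus:
    """Load a labeled corpus from ``jsonl`` (native dialect) or ``nbib``."""
    if format == "jsonl":
        return load_jsonl(path)
    if format == "nbib":
        return load_nbib(path)
    raise ValueError(f"unknown corpus format {format!r}")


# ---------------------------------------------------------------------------
# Journal-level splitting


def split_by_journal(
    corpus: LabeledCorpus, ratio: tuple[int, int] = (2, 1), seed: int = 0
) -> JournalSplit:
    """Randomly partition the corpus's journals into development/validation.

    Journals (not articles) are permuted with a seeded PCG64 generator
    (`numpy.random.default_rng`) and the first floor(n*r1/(r1+r2)) go to the
    development side.  The split is a function of (journal set, ratio, seed)
    only, so it is reproducible across platforms and record orderings.
    """
    r1, r2 = ratio
    if r1 <= 0 or r2 <= 0:
        raise ValueError(f"ratio components must be positive, got {ratio}")
    journals = sorted(corpus.journals)
    if len(journals) < 2:
        raise ValueError("corpus must contain at least 2 distinct journals")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(journals))
    n_dev = (len(journals) * r1) // (r1 + r2)
    shuffled = [journals[i] for i in perm]
    return JournalSplit(
        development_journals=frozenset(shuffled[:n_dev]),
        validation_journals=frozenset(shuffled[n_dev:]),
        seed=seed,
    )
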