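"""Synthetic labeled citation corpora with known class-conditional structure.

A real filter study rests on a manually reviewed reference standard — tens
of thousands of full-text relevance judgements that cannot be shipped.  This
module stands in for that corpus with a generative model whose ground truth
is known exactly, so retrieval machinery and the filter optimizer can be
tested against closed-form expectations.

Model: records are assigned to journals round-robin; each record is relevant
with probability ``prevalence`` (optionally shifted per journal).  For every
term profile, independently given the class: the term's text form appears in
the title (probability ``title_placement_prob``) or abstract with class
conditional probability p_text_rel / p_text_irr, choosing a surface form by
weight (so British/American spelling variants can share one profile); if the
profile names a descriptor, the record is indexed with it with probability
p_index_rel / p_index_irr, the index entry then being dropped with
probability ``indexing_dropout`` (indexing noise) and flagged major with
probability ``p_major_given_indexed``.  Remaining title/abstract text is
filler drawn from a vocabulary disjoint from all profile surfaces, so the
planted signal is unambiguous.

Because profiles are class-conditionally independent, the sensitivity and
specificity of any AND/OR/NOT query over distinct profiles has a closed form
(`expected_performance`), which the Monte-Carlo output must reproduce within
binomial error — the module's own correctness check and the oracle for
planted-term-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import CitationRecord, IndexTerm, LabeledCorpus
from .engine import _compile_phrase, tokenize
from .queryast import BooleanNode, ProximityNode, Query, TermLeaf


@dataclass(frozen=True)
class TermProfile:
    """Class-conditional occurrence model for one planted term."""

    surfaces: tuple = ()
    p_text_rel: float = 0.0
    p_text_irr: float = 0.0
    descriptor: str | None = None
    p_index_rel: float = 0.0
    p_index_irr: float = 0.0
    p_major_given_indexed: float = 0.5

    def __post_init__(self):
        surfaces = []
        for s in self.surfaces:
            if isinstance(s, str):
                surfaces.append((s, 1.0))
            else:
                surfaces.append((s[0], float(s[1])))
        object.__setattr__(self, "surfaces", tuple(surfaces))
        for name in ("p_text_rel", "p_text_irr", "p_index_rel",
                     "p_index_irr", "p_major_given_indexed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if (self.p_text_rel > 0 or self.p_text_irr > 0) and not self.surfaces:
            raise ValueError("profile with text occurrence needs surfaces")

    def surface_weight_fraction(self, matcher) -> float:
        """Fraction of surface-selection weight whose surface satisfies
        ``matcher(surface) -> bool``."""
        total = sum(w for _, w in self.surfaces)
        if total == 0:
            return 0.0
        hit = sum(w for s, w in self.surfaces if matcher(s))
        return hit / total


def default_profiles() -> tuple[TermProfile, ...]:
    """The study conditions used throughout testing: a handful of planted
    glomerular-disease terms with realistic class separation, including a
    descriptor-indexed term and a British/American spelling pair."""
    return (
        TermProfile(
            surfaces=("glomerulonephritis",),
            p_text_rel=0.55, p_text_irr=0.02,
            descriptor="Glomerulonephritis",
            p_index_rel=0.50, p_index_irr=0.01,
            p_major_given_indexed=0.6,
        ),
        TermProfile(surfaces=("proteinuria",), p_text_rel=0.45, p_text_irr=0.04),
        TermProfile(surfaces=("nephrotic syndrome",), p_text_rel=0.30, p_text_irr=0.01),
        TermProfile(
            surfaces=(("polyangiitis", 0.7), ("polyangitis", 0.3)),
            p_text_rel=0.15, p_text_irr=0.005,
        ),
        TermProfile(surfaces=("biopsy",), p_text_rel=0.35, p_text_irr=0.10),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    n_journals: int = 40
    articles_per_journal: int = 125
    prevalence: float = 0.05
    profiles: tuple[TermProfile, ...] = field(default_factory=default_profiles)
    filler_vocab_size: int = 200
    filler_terms_per_record: int = 12
    indexing_dropout: float = 0.10
    title_placement_prob: float = 0.30
    journal_prevalence_multipliers: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence outside [0, 1]")
        if self.n_journals < 2:
            raise ValueError("need at least 2 journals")
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if self.journal_prevalence_multipliers is not None:
            m = tuple(self.journal_prevalence_multipliers)
            if len(m) != self.n_journals:
                raise ValueError("one prevalence multiplier per journal required")
            object.__setattr__(self, "journal_prevalence_multipliers", m)

    @property
    def n_records(self) -> int:
        return self.n_journals * self.articles_per_journal


def generate(config: GeneratorConfig, thesaurus=None) -> LabeledCorpus:
    """Draw one corpus from the generative model; deterministic given seed."""
    for p in config.profiles:
        if p.descriptor is not None and thesaurus is not None:
            thesaurus.lookup(p.descriptor)  # raises KeyError if unresolvable
    rng = np.random.default_rng(config.seed)
    filler = [f"filler{i:04d}" for i in range(config.filler_vocab_size)]
    records, labels = [], {}
    for idx in range(config.n_records):
        j = idx % config.n_journals
        prev = config.prevalence
        if config.journal_prevalence_multipliers is not None:
            prev = min(1.0, prev * config.journal_prevalence_multipliers[j])
        relevant = bool(rng.random() < prev)
        title_words = list(rng.choice(filler, size=4))
        abstract_words = list(
            rng.choice(filler, size=config.filler_terms_per_record)
        )
        index_terms = []
        for prof in config.profiles:
            p_text = prof.p_text_rel if relevant else prof.p_text_irr
            if rng.random() < p_text:
                weights = np.array([w for _, w in prof.surfaces])
                k = int(rng.choice(len(prof.surfaces), p=weights / weights.sum()))
                surface = prof.surfaces[k][0]
                if rng.random() < config.title_placement_prob:
                    title_words.append(surface)
                else:
                    abstract_words.append(surface)
            if prof.descriptor is not None:
                p_idx = prof.p_index_rel if relevant else prof.p_index_irr
                if rng.random() < p_idx and not rng.random() < config.indexing_dropout:
                    index_terms.append(
                        IndexTerm(
                            descriptor_name=prof.descriptor,
                            major=bool(rng.random() < prof.p_major_given_indexed),
                        )
                    )
        uid = f"S{idx:06d}"
        records.append(
            CitationRecord(
                uid=uid,
                journal_id=f"J{j:03d}",
                pub_year=2004 + idx % 5,
                title=" ".join(title_words),
                abstract=" ".join(abstract_words) + ".",
                index_terms=tuple(index_terms),
                source_databases=frozenset({"pubmed", "medline", "embase"}),
            )
        )
        labels[uid] = relevant
    return LabeledCorpus(records, labels)


# ---------------------------------------------------------------------------
# Analytic expected performance


def _leaf_probability(leaf: TermLeaf, config: GeneratorConfig, relevant: bool,
                      thesaurus=None) -> float:
    """P(leaf matches | class), under the generator's independence model."""
    if leaf.kind == "descriptor":
        if thesaurus is not None:
            target = thesaurus.lookup(leaf.surface).name
            targets = thesaurus.descendants(target) if leaf.explode else {target}
            targets = {t.lower() for t in targets}
        else:
            targets = {leaf.surface.lower()}
        p_nomatch = 1.0
        hit = False
        for prof in config.profiles:
            if prof.descriptor is None or prof.descriptor.lower() not in targets:
                continue
            hit = True
            p = prof.p_index_rel if relevant else prof.p_index_irr
            p *= 1.0 - config.indexing_dropout
            if leaf.major:
                p *= prof.p_major_given_indexed
            p_nomatch *= 1.0 - p
        if not hit:
            raise ValueError(f"descriptor leaf {leaf.surface!r} maps to no profile")
        return 1.0 - p_nomatch

    matchers = _compile_phrase(leaf.surface, leaf.truncated)

    def surface_matches(surface: str) -> bool:
        toks = tokenize(surface)
        return len(toks) == len(matchers) and all(
            m(t) for m, t in zip(matchers, toks)
        )

    field = leaf.field or "tw"
    p_nomatch = 1.0
    hit = False
    for prof in config.profiles:
        frac = prof.surface_weight_fraction(surface_matches)
        p_events = []
        if frac > 0 and prof.surfaces:
            hit = True
            p_text = (prof.p_text_rel if relevant else prof.p_text_irr) * frac
            if field == "ti":
                p_text *= config.title_placement_prob
            p_events.append(p_text)
        if (
            field in ("tw", "mp")
            and prof.descriptor is not None
            and surface_matches(prof.descriptor)
        ):
            # text-word fields also see the indexing-derived descriptor name
            hit = True
            p_idx = prof.p_index_rel if relevant else prof.p_index_irr
            p_events.append(p_idx * (1.0 - config.indexing_dropout))
        for p in p_events:
            p_nomatch *= 1.0 - p
    if not hit:
        raise ValueError(f"text leaf {leaf.surface!r} maps to no profile")
    return 1.0 - p_nomatch


def _match_probability(node, config, relevant, thesaurus=None) -> float:
    if isinstance(node, TermLeaf):
        return _leaf_probability(node, config, relevant, thesaurus)
    if isinstance(node, ProximityNode):
        raise ValueError("expected_performance does not support proximity nodes")
    if isinstance(node, BooleanNode):
        ps = [_match_probability(c, config, relevant, thesaurus) for c in node.children]
        if node.op == "OR":
            out = 1.0
            for p in ps:
                out *= 1.0 - p
            return 1.0 - out
        if node.op == "AND":
            out = 1.0
            for p in ps:
                out *= p
            return out
        pa, pb = ps
        return pa * (1.0 - pb)
    if isinstance(node, Query):
        return _match_probability(node.root, config, relevant, thesaurus)
    raise TypeError(f"not a query node: {node!r}")


def expected_performance(query, config: GeneratorConfig, thesaurus=None):
    """Closed-form (sensitivity, specificity) of an AND/OR/NOT query over the
    generator's independent profile events.

    Assumes each profile backs at most one leaf per conjunction path (leaves
    over the *same* profile are treated as independent, which they are not);
    queries over distinct profiles are exact.
    """
    se = _match_probability(query, config, relevant=True, thesaurus=thesaurus)
    fp = _match_probability(query, config, relevant=False, thesaurus=thesaurus)
    return se, 1.0 - fp


def config_from_yaml(path) -> GeneratorConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        obj = yaml.safe_load(fh) or {}
    profiles = obj.pop("profiles", None)
    if profiles is not None:
        obj["profiles"] = tuple(
            TermProfile(
                surfaces=tuple(
                    (s["surface"], s.get("weight", 1.0)) if isinstance(s, dict) else s
                    for s in p.get("surfaces", ())
                ),
                p_text_rel=p.get("p_text_rel", 0.0),
                p_text_irr=p.get("p_text_irr", 0.0),
                descriptor=p.get("descriptor"),
                p_index_rel=p.get("p_index_rel", 0.0),
                p_index_irr=p.get("p_index_irr", 0.0),
                p_major_given_indexed=p.get("p_major_given_indexed", 0.5),
            )
            for p in profiles
        )
    if "journal_prevalence_multipliers" in obj and obj["journal_prevalence_multipliers"]:
        obj["journal_prevalence_multipliers"] = tuple(
            obj["journal_prevalence_multipliers"]
        )
    return GeneratorConfig(**obj)
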