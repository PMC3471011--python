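"""Automated filter combination: candidate enumeration, screening, beam search.

The published multi-term filters all share one shape: a large OR whose
clauses are single terms or two-way conjunctions of terms/OR-groups.  The
optimizer here searches exactly that space.  Starting from the screened
single-term candidates it grows an OR-of-clauses query, at each step either
adding an OR clause (pushing sensitivity up) or — when enabled — refining an
existing clause with AND or NOT (pushing specificity up), keeping the
``beam_width`` best states under the chosen objective.  The beam is
best-first across clause counts: each round ranks the union of the current
beam and all proposals, so with a beam at least as wide as the candidate
pool the search degenerates to exhaustive enumeration over small pools.

Objectives:

- ``youden``  maximize sensitivity + specificity - 1 (balanced)
- ``sens``    maximize sensitivity subject to specificity >= spec_floor
- ``spec``    maximize specificity subject to sensitivity >= sens_floor

`FilterDeveloper` is the model object (corpus + thesaurus + candidate terms
+ config); `.fit()` runs the search and returns `DevelopmentResults`
carrying the frontier of developed filters with their contingency tables,
metrics and confidence intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from . import engine
from .diagnostics import ContingencyTable, DiagnosticPerformance, performance
from .queryast import BooleanNode, Query, TermLeaf, count_leaves, to_string

OBJECTIVES = ("youden", "sens", "spec")


@dataclass(frozen=True)
class CandidateTerm:
    """A raw term from the term-gathering phase, before variant expansion."""

    base: str
    has_descriptor: bool = False
    allowed_fields: tuple[str, ...] = ("tw",)
    allow_truncation: bool = True

    def __post_init__(self):
        object.__setattr__(self, "allowed_fields", tuple(self.allowed_fields))
        if not self.has_descriptor and not self.allowed_fields:
            raise ValueError(f"term {self.base!r} enables no variant axis")


@dataclass(frozen=True)
class FilterCandidate:
    query: Query
    table: ContingencyTable
    performance: DiagnosticPerformance

    @property
    def sensitivity(self) -> float:
        m = self.performance.sensitivity
        return m.point if m else 0.0

    @property
    def specificity(self) -> float:
        m = self.performance.specificity
        return m.point if m else 0.0

    @property
    def precision(self) -> float:
        m = self.performance.precision
        return m.point if m else 0.0

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    @property
    def n_leaves(self) -> int:
        return count_leaves(self.query)

    @property
    def source_text(self) -> str:
        return self.query.source_text or to_string(self.query)


@dataclass(frozen=True)
class DevelopConfig:
    objective: str = "youden"
    spec_floor: float = 0.0
    sens_floor: float = 0.0
    beam_width: int = 10
    max_or_clauses: int = 10
    allow_and_refinement: bool = True
    allow_not: bool = False
    screen_min_sens: float = 0.10
    screen_min_spec: float = 0.90
    epsilon: float = 1e-9
    seed: int = 0

    def __post_init__(self):
        if self.objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective!r}")
        if not (0.0 <= self.spec_floor <= 1.0 and 0.0 <= self.sens_floor <= 1.0):
            raise ValueError("floors must lie in [0, 1]")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


# ---------------------------------------------------------------------------
# Variant enumeration


def enumerate_variants(terms, dialect: str, thesaurus=None) -> list[Query]:
    """Expand candidate terms along the variant axes used in filter building:
    each allowed text field x {plain, truncated}, and for descriptor terms
    additionally {heading, major-topic} x {exploded, unexploded}."""
    out: list[Query] = []
    seen: set[Query] = set()

    def emit(leaf: TermLeaf):
        q = Query(root=leaf, dialect=dialect)
        q = dataclasses.replace(q, source_text=to_string(q))
        if q not in seen:
            seen.add(q)
            out.append(q)

    for term in terms:
        if term.has_descriptor:
            if thesaurus is None or term.base not in thesaurus:
                raise ValueError(
                    f"descriptor term {term.base!r} not found in thesaurus"
                )
            canonical = thesaurus.lookup(term.base).name
            for major in (False, True):
                for explode in (True, False):
                    emit(
                        TermLeaf(
                            kind="descriptor", surface=canonical, field="mh",
                            explode=explode, major=major,
                        )
                    )
        for f in term.allowed_fields:
            states = (False, True) if term.allow_truncation else (False,)
            for truncated in states:
                emit(
                    TermLeaf(
                        kind="text", surface=term.base, field=f,
                        truncated=truncated, wildcard="?" in term.base,
                    )
                )
    return out


def load_term_file(path) -> list[CandidateTerm]:
    """TSV term list: base <tab> has_descriptor <tab> comma-joined fields
    <tab> allow_truncation."""
    terms = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            base = parts[0].strip()
            has_desc = len(parts) > 1 and parts[1].strip().lower() in ("1", "true", "yes")
            fields = ("tw",)
            if len(parts) > 2 and parts[2].strip():
                fields = tuple(f.strip() for f in parts[2].split(",") if f.strip())
            trunc = True
            if len(parts) > 3:
                trunc = parts[3].strip().lower() in ("1", "true", "yes")
            terms.append(CandidateTerm(base, has_desc, fields, trunc))
    return terms


# ---------------------------------------------------------------------------
# Screening


def _evaluate_query(query, corpus, thesaurus, ci_method="wald") -> FilterCandidate:
    from .diagnostics import contingency

    retrieved = engine.retrieve(query, corpus, thesaurus)
    table = contingency(retrieved, corpus)
    return FilterCandidate(query, table, performance(table, ci_method=ci_method))


def _screen_sort_key(cand: FilterCandidate):
    return (-cand.youden, cand.n_leaves, cand.source_text)


def screen(candidates, corpus, thesaurus=None, config: DevelopConfig | None = None):
    """Evaluate every candidate query on the corpus and keep those clearing
    the sensitivity OR the specificity screen; sort by Youden index
    (ties: fewer leaves, then source text)."""
    config = config or DevelopConfig()
    survivors = []
    for q in candidates:
        cand = _evaluate_query(q, corpus, thesaurus)
        if (
            cand.sensitivity >= config.screen_min_sens
            or cand.specificity >= config.screen_min_spec
        ):
            survivors.append(cand)
    survivors.sort(key=_screen_sort_key)
    return survivors


# ---------------------------------------------------------------------------
# Beam search


def _clause_query(variants, clause, dialect) -> object:
    """AST node for one clause. Clause encodings:
    ("atom", i) | ("and", i, j) | ("not", i, j)."""
    kind = clause[0]
    if kind == "atom":
        return variants[clause[1]].root
    a, b = variants[clause[1]].root, variants[clause[2]].root
    return BooleanNode("AND" if kind == "and" else "NOT", (a, b))


def _state_query(variants, state, dialect) -> Query:
    nodes = [_clause_query(variants, c, dialect) for c in state]
    root = nodes[0] if len(nodes) == 1 else BooleanNode("OR", nodes)
    q = Query(root=root, dialect=dialect)
    return dataclasses.replace(q, source_text=to_string(q))


class _Objective:
    def __init__(self, config: DevelopConfig):
        self.config = config

    def value(self, sens: float, spec: float) -> float:
        if self.config.objective == "youden":
            return sens + spec - 1.0
        if self.config.objective == "sens":
            return sens
        return spec

    def feasible(self, sens: float, spec: float) -> bool:
        if self.config.objective == "sens":
            return spec >= self.config.spec_floor
        if self.config.objective == "spec":
            return sens >= self.config.sens_floor
        return True


class _State:
    """A candidate filter during search: a sorted tuple of clauses plus its
    retrieved set and metrics on the development corpus."""

    __slots__ = ("clauses", "uids", "sens", "spec", "n_leaves", "text")

    def __init__(self, clauses, uids, n_rel, n_irr, variants, dialect):
        self.clauses = tuple(sorted(clauses))
        self.uids = uids
        a = len(uids & _State._relevant)
        b = len(uids) - a
        self.sens = a / n_rel if n_rel else 0.0
        self.spec = 1.0 - (b / n_irr if n_irr else 0.0)
        self.n_leaves = sum(1 if c[0] == "atom" else 2 for c in self.clauses)
        self.text = " | ".join(map(str, self.clauses))

    _relevant: frozenset = frozenset()


def _clause_uids(variant_uids, clause) -> frozenset:
    kind = clause[0]
    if kind == "atom":
        return variant_uids[clause[1]]
    a, b = variant_uids[clause[1]], variant_uids[clause[2]]
    return a & b if kind == "and" else a - b


class FilterDeveloper:
    """Model object: a labeled development corpus plus a candidate-term pool.

    Parameters
    ----------
    corpus : LabeledCorpus
        The development view (labels required).
    thesaurus : Thesaurus or None
        Resolves descriptor candidates.
    terms : list of CandidateTerm, optional
        Expanded via `enumerate_variants`; alternatively pass pre-built
        queries via ``candidates``.
    config : DevelopConfig
    dialect : str
        Dialect for generated queries (default pubmed).
    """

    def __init__(self, corpus, thesaurus=None, terms=None, candidates=None,
                 config=None, dialect="pubmed"):
        if corpus.labels is None:
            raise ValueError("filter development requires a labeled corpus")
        self.corpus = corpus
        self.thesaurus = thesaurus
        self.config = config or DevelopConfig()
        self.dialect = dialect
        if candidates is None:
            if not terms:
                raise ValueError("provide candidate terms or queries")
            candidates = enumerate_variants(terms, dialect, thesaurus)
        self.candidates = list(candidates)

    @classmethod
    def from_term_file(cls, corpus, path, thesaurus=None, config=None,
                       dialect="pubmed"):
        return cls(corpus, thesaurus, terms=load_term_file(path),
                   config=config, dialect=dialect)

    def fit(self) -> "DevelopmentResults":
        cfg = self.config
        screened = screen(self.candidates, self.corpus, self.thesaurus, cfg)
        if not screened:
            raise ValueError("screened candidate pool is empty")
        variants = [c.query for c in screened]
        variant_uids = [
            frozenset(engine.retrieve(q, self.corpus, self.thesaurus))
            for q in variants
        ]
        relevant = frozenset(self.corpus.relevant_uids)
        n_rel = len(relevant)
        n_irr = len(self.corpus) - n_rel
        obj = _Objective(cfg)

        _State._relevant = relevant  # class-level context for cheap scoring

        def make_state(clauses):
            uids = frozenset().union(
                *(_clause_uids(variant_uids, c) for c in clauses)
            )
            return _State(clauses, uids, n_rel, n_irr, variants, self.dialect)

        def rank_key(s: _State):
            return (
                not obj.feasible(s.sens, s.spec),
                -obj.value(s.sens, s.spec),
                s.n_leaves,
                s.text,
            )

        n_var = len(variants)
        beam = sorted(
            (make_state((("atom", i),)) for i in range(n_var)), key=rank_key
        )[: cfg.beam_width]
        seen = {s.clauses for s in beam}
        best = beam[0]

        for _ in range(cfg.max_or_clauses + 2):
            proposals = []
            for s in beam:
                base_set = set(s.clauses)
                if len(s.clauses) < cfg.max_or_clauses:
                    for i in range(n_var):
                        cl = ("atom", i)
                        if cl in base_set:
                            continue
                        new = s.clauses + (cl,)
                        key = tuple(sorted(new))
                        if key not in seen:
                            seen.add(key)
                            ns = make_state(new)
                            # OR-addition moves along the expected axes
                            assert ns.sens >= s.sens - 1e-12
                            assert ns.spec <= s.spec + 1e-12
                            proposals.append(ns)
                refinements = []
                if cfg.allow_and_refinement:
                    refinements.append("and")
                if cfg.allow_not:
                    refinements.append("not")
                for kind in refinements:
                    for ci, cl in enumerate(s.clauses):
                        if cl[0] != "atom":
                            continue
                        for j in range(n_var):
                            if j == cl[1]:
                                continue
                            new = list(s.clauses)
                            new[ci] = (kind, cl[1], j)
                            key = tuple(sorted(new))
                            if key not in seen:
                                seen.add(key)
                                ns = make_state(new)
                                assert ns.sens <= s.sens + 1e-12
                                assert ns.spec >= s.spec - 1e-12
                                proposals.append(ns)
            if not proposals:
                break
            beam = sorted(beam + proposals, key=rank_key)[: cfg.beam_width]
            new_best = beam[0]
            improved = obj.value(new_best.sens, new_best.spec) - obj.value(
                best.sens, best.spec
            )
            gained_feasibility = obj.feasible(
                new_best.sens, new_best.spec
            ) and not obj.feasible(best.sens, best.spec)
            if improved < cfg.epsilon and not gained_feasibility:
                best = min((best, new_best), key=rank_key)
                break
            best = new_best

        frontier = []
        for s in beam:
            q = _state_query(variants, s.clauses, self.dialect)
            frontier.append(_evaluate_query(q, self.corpus, self.thesaurus))
        frontier.sort(
            key=lambda c: (
                not obj.feasible(c.sensitivity, c.specificity),
                -obj.value(c.sensitivity, c.specificity),
                c.n_leaves,
                c.source_text,
            )
        )
        infeasible = not obj.feasible(frontier[0].sensitivity, frontier[0].specificity)
        return DevelopmentResults(self, frontier, infeasible)


class DevelopmentResults:
    """Fitted search output: the beam frontier as evaluated FilterCandidates."""

    def __init__(self, model: FilterDeveloper, frontier, infeasible: bool):
        self.model = model
        self.frontier = frontier
        self.infeasible = infeasible

    @property
    def best(self) -> FilterCandidate:
        return self.frontier[0]

    def evaluate(self, corpus, ci_method="wald") -> FilterCandidate:
        """Score the best developed filter on a held-out (validation) corpus.

        Intended to be called exactly once, on the validation view, after
        development is frozen — the two-phase design."""
        return _evaluate_query(
            self.best.query, corpus, self.model.thesaurus, ci_method=ci_method
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.frontier:
            t = c.table
            rows.append(
                {
                    "filter": c.source_text,
                    "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                    "sensitivity": c.sensitivity,
                    "specificity": c.specificity,
                    "precision": c.precision,
                    "accuracy": c.performance.accuracy.point,
                    "youden": c.youden,
                    "n_leaves": c.n_leaves,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def develop_filter(corpus, thesaurus=None, terms=None, config=None,
                   candidates=None, dialect="pubmed"):
    """Functional wrapper: build a FilterDeveloper, fit, return the frontier."""
    model = FilterDeveloper(
        corpus, thesaurus, terms=terms, candidates=candidates,
        config=config, dialect=dialect,
    )
    return model.fit()


# ---------------------------------------------------------------------------
# Pareto frontier


def pareto_frontier(candidates) -> list[FilterCandidate]:
    """Candidates not dominated in (sensitivity, specificity), sorted by
    descending sensitivity; ties broken by precision then leaf count."""
    out = []
    for c in candidates:
        dominated = any(
            (o.sensitivity >= c.sensitivity and o.specificity >= c.specificity)
            and (o.sensitivity > c.sensitivity or o.specificity > c.specificity)
            for o in candidates
        )
        if not dominated:
            out.append(c)
    out.sort(key=lambda c: (-c.sensitivity, -c.precision, c.n_leaves))
    return out
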