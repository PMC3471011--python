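import random

import pytest

from filtercraft.corpus import LabeledCorpus
from filtercraft.development import (
    CandidateTerm,
    DevelopConfig,
    FilterDeveloper,
    develop_filter,
    enumerate_variants,
    pareto_frontier,
    screen,
)
from filtercraft.engine import retrieve
from filtercraft.parsers import parse_pubmed
from filtercraft.queryast import count_leaves

from _oracles import exhaustive_or_search
from conftest import make_record


def marker_corpus(spec):
    """spec: list of (title, relevant) pairs replicated into a corpus."""
    records, labels = [], {}
    for i, (title, relevant) in enumerate(spec):
        uid = f"m{i:04d}"
        records.append(make_record(uid=uid, title=title, journal_id=f"J{i % 3}"))
        labels[uid] = relevant
    return LabeledCorpus(records, labels)


class TestEnumerateVariants:
    def test_empty_input(self):
        assert enumerate_variants([], "pubmed") == []

    def test_text_term_field_by_truncation_grid(self):
        terms = [CandidateTerm("nephritis", allowed_fields=("tw", "tiab", "ti"),
                               allow_truncation=True)]
        variants = enumerate_variants(terms, "pubmed")
        assert len(variants) == 6  # 3 fields x {plain, truncated}

    def test_descriptor_term_adds_heading_variants(self, mesh):
        terms = [CandidateTerm("Glomerulonephritis", has_descriptor=True,
                               allowed_fields=("tw",), allow_truncation=True)]
        variants = enumerate_variants(terms, "pubmed", mesh)
        # 2 text (plain/truncated) + {mh, majr} x {explode, noexp}
        assert len(variants) == 6
        kinds = [v.root.kind for v in variants]
        assert kinds.count("descriptor") == 4

    def test_duplicate_asts_removed(self):
        terms = [CandidateTerm("kidney", allowed_fields=("tw",), allow_truncation=False)] * 2
        assert len(enumerate_variants(terms, "pubmed")) == 1

    def test_missing_descriptor_is_error(self, mesh):
        with pytest.raises(ValueError, match="Nonexistent"):
            enumerate_variants(
                [CandidateTerm("Nonexistent", has_descriptor=True)], "pubmed", mesh
            )


class TestScreen:
    def test_counting_oracle_example(self, tiny_corpus, mesh):
        cands = screen([parse_pubmed("marker[tw]")], tiny_corpus, mesh)
        (c,) = cands
        assert c.sensitivity == pytest.approx(0.90)
        assert c.specificity == pytest.approx(0.95)

    def test_nothing_retrieved_is_fully_specific(self, tiny_corpus, mesh):
        cands = screen(
            [parse_pubmed("absent[tw]")], tiny_corpus, mesh,
            DevelopConfig(screen_min_sens=0.0, screen_min_spec=0.0),
        )
        (c,) = cands
        assert c.sensitivity == 0.0 and c.specificity == 1.0

    def test_failing_both_screens_is_dropped(self, tiny_corpus, mesh):
        # 'noise' occurs in 1/10 relevant and 96/100 irrelevant records
        cfg = DevelopConfig(screen_min_sens=0.5, screen_min_spec=0.9)
        assert screen([parse_pubmed("noise[tw]")], tiny_corpus, mesh, cfg) == []

    def test_tie_break_is_stable(self, tiny_corpus, mesh):
        qs = [parse_pubmed("marker study[tw] OR marker noise[tw]"),
              parse_pubmed("marker[tw]")]
        for ordering in (qs, qs[::-1]):
            ranked = screen(list(ordering), tiny_corpus, mesh)
            # equal Youden; the single-leaf candidate wins the tie
            assert count_leaves(ranked[0].query) == 1


class TestDevelopFilter:
    def test_perfect_marker_single_clause(self, mesh):
        corpus = marker_corpus(
            [("perfect marker", True)] * 20 + [("something else", False)] * 80
        )
        res = develop_filter(
            corpus, mesh,
            terms=[CandidateTerm("perfect", allowed_fields=("tw",)),
                   CandidateTerm("something", allowed_fields=("tw",))],
            config=DevelopConfig(objective="youden", beam_width=8),
        )
        assert res.best.sensitivity == 1.0 and res.best.specificity == 1.0
        assert count_leaves(res.best.query) == 1

    def test_complementary_terms_combine_with_or(self, mesh):
        spec = [("alpha present", True)] * 10 + [("beta present", True)] * 10
        spec += [("background only", False)] * 80
        corpus = marker_corpus(spec)
        terms = [CandidateTerm(w, allowed_fields=("tw",), allow_truncation=False)
                 for w in ("alpha", "beta", "background")]
        res = develop_filter(
            corpus, mesh, terms=terms,
            config=DevelopConfig(objective="youden", beam_width=8, max_or_clauses=2),
        )
        assert res.best.sensitivity == 1.0 and res.best.specificity == 1.0
        # equals the exhaustive optimum over all <=2-clause OR filters
        variants = enumerate_variants(terms, "pubmed")
        uid_sets = [retrieve(v, corpus, mesh) for v in variants]
        best = exhaustive_or_search(uid_sets, corpus.relevant_uids, len(corpus), 2)
        assert res.best.youden == pytest.approx(best[0])

    def test_and_refinement_beats_single_terms(self, mesh):
        rnd = random.Random(17)
        spec = [("alpha beta joint", True) for _ in range(30)]
        for _ in range(170):
            words = []
            if rnd.random() < 0.3:
                words.append("alpha")
            if rnd.random() < 0.3:
                words.append("beta")
            words.append("filler")
            spec.append((" ".join(words), False))
        corpus = marker_corpus(spec)
        terms = [CandidateTerm(w, allowed_fields=("tw",), allow_truncation=False)
                 for w in ("alpha", "beta")]
        res = develop_filter(
            corpus, mesh, terms=terms,
            config=DevelopConfig(objective="youden", beam_width=8,
                                 allow_and_refinement=True, max_or_clauses=1,
                                 screen_min_sens=0.0, screen_min_spec=0.0),
        )
        best = res.best
        assert best.query.root.op == "AND"
        singles = screen([parse_pubmed("alpha[tw]"), parse_pubmed("beta[tw]")],
                         corpus, mesh,
                         DevelopConfig(screen_min_sens=0, screen_min_spec=0))
        assert best.specificity > max(s.specificity for s in singles)
        # counting oracle: AND retrieves exactly the joint records
        assert best.table.a == 30 and best.sensitivity == 1.0

    def test_matches_exhaustive_search_on_random_corpora(self, mesh):
        rnd = random.Random(23)
        words = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
        for trial in range(5):
            spec = []
            for i in range(150):
                rel = rnd.random() < 0.3
                present = [
                    w for j, w in enumerate(words)
                    if rnd.random() < (0.15 + 0.5 * rel * ((j % 3) == trial % 3)
                                       if rel else 0.1 + 0.05 * j / len(words))
                ]
                spec.append((" ".join(present) or "empty", rel))
            corpus = marker_corpus(spec)
            terms = [CandidateTerm(w, allowed_fields=("tw",), allow_truncation=False)
                     for w in words]
            variants = enumerate_variants(terms, "pubmed")
            uid_sets = [retrieve(v, corpus, mesh) for v in variants]
            oracle = exhaustive_or_search(
                uid_sets, corpus.relevant_uids, len(corpus), 3
            )
            res = develop_filter(
                corpus, mesh, terms=terms,
                config=DevelopConfig(
                    objective="youden", beam_width=64, max_or_clauses=3,
                    allow_and_refinement=False,
                    screen_min_sens=0.0, screen_min_spec=0.0,
                ),
            )
            assert res.best.youden == pytest.approx(oracle[0])

    def test_objective_floor_feasibility(self, tiny_corpus, mesh):
        terms = [CandidateTerm("marker", allowed_fields=("tw",),
                               allow_truncation=False)]
        feasible = develop_filter(
            tiny_corpus, mesh, terms=terms,
            config=DevelopConfig(objective="sens", spec_floor=0.9, beam_width=4),
        )
        assert not feasible.infeasible
        infeasible = develop_filter(
            tiny_corpus, mesh, terms=terms,
            config=DevelopConfig(objective="sens", spec_floor=0.999, beam_width=4,
                                 screen_min_sens=0.0, screen_min_spec=0.0),
        )
        assert infeasible.infeasible  # best-effort frontier still returned
        assert infeasible.frontier

    def test_deterministic(self, tiny_corpus, mesh):
        terms = [CandidateTerm(w, allowed_fields=("tw",))
                 for w in ("marker", "study", "noise")]
        cfg = DevelopConfig(objective="youden", beam_width=6)
        r1 = develop_filter(tiny_corpus, mesh, terms=terms, config=cfg)
        r2 = develop_filter(tiny_corpus, mesh, terms=terms, config=cfg)
        assert [c.source_text for c in r1.frontier] == [
            c.source_text for c in r2.frontier
        ]

    def test_empty_pool_is_error(self, tiny_corpus, mesh):
        # 'noise' hits 1/10 relevant and 96/100 irrelevant: fails both screens
        with pytest.raises(ValueError, match="empty"):
            develop_filter(
                tiny_corpus, mesh,
                terms=[CandidateTerm("noise", allowed_fields=("tw",),
                                     allow_truncation=False)],
                config=DevelopConfig(screen_min_sens=0.5, screen_min_spec=0.9),
            ).best

    def test_validation_evaluation_uses_heldout_corpus(self, mesh):
        dev = marker_corpus([("marker yes", True)] * 10 + [("no", False)] * 40)
        val = marker_corpus([("marker yes", True)] * 5 + [("marker no", False)] * 45)
        res = develop_filter(
            dev, mesh,
            terms=[CandidateTerm("marker", allowed_fields=("tw",))],
            config=DevelopConfig(objective="youden", beam_width=2),
        )
        held = res.evaluate(val)
        assert held.sensitivity == 1.0
        assert held.specificity == 0.0  # every validation record carries the term

    def test_summary_table_shape(self, tiny_corpus, mesh):
        res = develop_filter(
            tiny_corpus, mesh,
            terms=[CandidateTerm("marker", allowed_fields=("tw",))],
            config=DevelopConfig(beam_width=3),
        )
        df = res.summary()
        assert {"filter", "a", "b", "c", "d", "sensitivity", "specificity",
                "precision", "accuracy", "youden", "n_leaves"} <= set(df.columns)
        assert len(df) == len(res.frontier)


class TestParetoFrontier:
    def _cand(self, mesh, corpus, text):
        (c,) = screen([parse_pubmed(text)], corpus, mesh,
                      DevelopConfig(screen_min_sens=0, screen_min_spec=0))
        return c

    def test_single_candidate_is_its_own_frontier(self, tiny_corpus, mesh):
        c = self._cand(mesh, tiny_corpus, "marker[tw]")
        assert pareto_frontier([c]) == [c]

    def test_dominated_candidate_removed(self, tiny_corpus, mesh):
        # same sensitivity (0.9) but 'marker study' is a strict phrase that
        # skips the irrelevant 'marker noise' records: it dominates 'marker'
        phrase = self._cand(mesh, tiny_corpus, "marker study[tw]")
        loose = self._cand(mesh, tiny_corpus, "marker[tw]")
        assert phrase.sensitivity == loose.sensitivity
        assert phrase.specificity > loose.specificity
        assert pareto_frontier([phrase, loose]) == [phrase]

    def test_matches_quadratic_dominance_oracle(self, mesh):
        rnd = random.Random(31)
        spec = []
        for i in range(120):
            rel = rnd.random() < 0.4
            words = [w for w in ("a1", "b2", "c3", "d4")
                     if rnd.random() < (0.6 if rel else 0.25)]
            spec.append((" ".join(words) or "none", rel))
        corpus = marker_corpus(spec)
        cands = [self._cand(mesh, corpus, f"{w}[tw]") for w in ("a1", "b2", "c3", "d4")]
        front = pareto_frontier(cands)
        expected = [
            c for c in cands
            if not any(
                (o.sensitivity >= c.sensitivity and o.specificity >= c.specificity
                 and (o.sensitivity > c.sensitivity or o.specificity > c.specificity))
                for o in cands
            )
        ]
        assert set(id(c) for c in front) == set(id(c) for c in expected)
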