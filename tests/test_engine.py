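import dataclasses
import random

import pytest

from filtercraft.corpus import IndexTerm, LabeledCorpus
from filtercraft.engine import matches, retrieve
from filtercraft.parsers import parse, parse_ovid, parse_pubmed
from filtercraft.queryast import BooleanNode, Query, TermLeaf

from _oracles import naive_retrieve, random_corpus, random_query
from conftest import make_record


class TestFieldSemantics:
    def test_adjacency_on_title(self, mesh):
        rec = make_record(title="Diabetic kidney disease and outcomes")
        q = parse_ovid("(diabetic adj (kidney or renal)).mp")
        assert matches(q, rec, mesh)
        assert not matches(q, make_record(title="diabetic care of the kidney"), mesh)

    def test_adj2_allows_one_intervening_token_either_order(self, mesh):
        q = parse_ovid("(chronic adj2 (kidney or renal)).mp")
        assert matches(q, make_record(title="chronic progressive kidney disease"), mesh)
        assert matches(q, make_record(title="kidney disease chronic stage"), mesh)
        assert not matches(q, make_record(title="chronic and very slow kidney disease"), mesh)

    def test_explosion_semantics(self, mesh):
        rec = make_record(
            title="case report",
            index_terms=(IndexTerm("IgA Nephropathy"),),
        )
        assert matches(parse_pubmed("Kidney Diseases[mh]"), rec, mesh)
        assert not matches(parse_pubmed("Kidney Diseases[mh:noexp]"), rec, mesh)

    def test_major_flag_required(self, mesh):
        minor = make_record(title="t", index_terms=(IndexTerm("Proteinuria"),))
        major = make_record(title="t", index_terms=(IndexTerm("Proteinuria", major=True),))
        q = parse_pubmed('"Proteinuria"[majr]')
        assert matches(q, major, mesh) and not matches(q, minor, mesh)

    def test_subheading_required_when_set(self, mesh):
        rec = make_record(
            title="t",
            index_terms=(IndexTerm("Glomerulonephritis", subheadings=("therapy",)),),
        )
        with_sub = TermLeaf(kind="descriptor", surface="Glomerulonephritis",
                            field="mh", explode=True, subheading="therapy")
        wrong_sub = dataclasses.replace(with_sub, subheading="diagnosis")
        assert matches(Query(with_sub, "pubmed"), rec, mesh)
        assert not matches(Query(wrong_sub, "pubmed"), rec, mesh)

    @pytest.mark.parametrize("word, hit", [
        ("polyangiitis", True), ("polyangitis", True), ("polyangiiitis", False),
    ])
    def test_wildcard_matches_zero_or_one_char(self, mesh, word, hit):
        q = parse_ovid("polyang?itis.mp")
        assert matches(q, make_record(title=f"renal {word} study"), mesh) is hit

    def test_truncation_is_prefix_on_final_token(self, mesh):
        q = parse_pubmed("glomerular disease*[tiab]")
        assert matches(q, make_record(title="glomerular diseases of childhood"), mesh)
        assert not matches(q, make_record(title="glomerular and renal disease"), mesh)

    def test_hyphen_splits_into_phrase(self, mesh):
        q = parse_pubmed("anti-glomerular[tw]")
        assert matches(q, make_record(title="anti-glomerular antibodies"), mesh)
        assert matches(q, make_record(title="anti glomerular antibodies"), mesh)
        assert not matches(q, make_record(title="antiglomerular antibodies"), mesh)

    def test_journal_name_never_satisfies_text_terms(self, mesh):
        rec = make_record(title="unrelated work", journal_id="Kidney International")
        assert not matches(parse_pubmed("kidney[tw]"), rec, mesh)
        assert matches(parse_pubmed("kidney international[jn]"), rec, mesh)

    def test_tw_sees_indexing_text_but_tiab_does_not(self, mesh):
        rec = make_record(
            title="plain title",
            index_terms=(IndexTerm("Glomerulonephritis"),),
            entry_term_strings=("membranous nephropathy",),
        )
        assert matches(parse_pubmed("glomerulonephritis[tw]"), rec, mesh)
        assert not matches(parse_pubmed("glomerulonephritis[tiab]"), rec, mesh)
        assert matches(parse_pubmed("membranous nephropathy[tw]"), rec, mesh)

    def test_classification_code_exact_match(self, emtree):
        rec = make_record(title="t", classification_codes=("Urology and Nephrology",))
        q = parse_ovid('"Urology and nephrology".ec', "ovid_embase")
        assert matches(q, rec, emtree)
        q2 = parse_ovid('"Urology".ec', "ovid_embase")
        assert not matches(q2, rec, emtree)

    def test_unresolvable_query_descriptor_is_an_error(self, mesh):
        q = parse_pubmed("No Such Heading[mh]")
        with pytest.raises(KeyError, match="No Such Heading"):
            matches(q, make_record(), mesh)


class TestRetrieve:
    def test_empty_and_singleton(self, mesh, tiny_corpus):
        assert retrieve(parse_pubmed("absentterm[tw]"), tiny_corpus, mesh) == set()
        one = LabeledCorpus([make_record(title="marker here")])
        assert retrieve(parse_pubmed("marker[tw]"), one, mesh) == {"r1"}

    def test_boolean_set_algebra(self, mesh):
        rnd = random.Random(11)
        a = parse_pubmed("kidney[tw]")
        b = parse_pubmed("lupus[tw]")
        for trial in range(25):
            corpus = random_corpus(rnd, n_records=40, thesaurus=mesh)
            ra = retrieve(a, corpus, mesh)
            rb = retrieve(b, corpus, mesh)
            assert retrieve(parse_pubmed("kidney[tw] OR lupus[tw]"), corpus, mesh) == ra | rb
            assert retrieve(parse_pubmed("kidney[tw] AND lupus[tw]"), corpus, mesh) == ra & rb
            assert retrieve(parse_pubmed("kidney[tw] NOT lupus[tw]"), corpus, mesh) == ra - rb


class TestOracleEquivalence:
    def test_evaluator_agrees_with_naive_set_algebra(self, mesh):
        rnd = random.Random(2012)
        vocab = ["kidney", "renal", "lupus", "biopsy", "nephrotic", "chronic",
                 "diabetic", "proteinuria", "vasculitis", "disease"]
        disagreements = 0
        for trial in range(8):
            corpus = random_corpus(rnd, n_records=50, thesaurus=mesh)
            for _ in range(25):
                q = random_query(rnd, vocab, thesaurus=mesh)
                if retrieve(q, corpus, mesh) != naive_retrieve(q, corpus, mesh):
                    disagreements += 1
        assert disagreements == 0

    def test_proximity_agrees_with_exhaustive_scan(self, mesh):
        rnd = random.Random(77)
        queries = [
            parse_ovid("(diabetic adj (kidney or renal)).mp"),
            parse_ovid("(chronic adj2 (kidney or renal)).mp"),
            parse_ovid("((kidney or renal) adj biopsy).mp"),
            parse_ovid("(chronic adj3 disease).ti"),
        ]
        for trial in range(10):
            corpus = random_corpus(rnd, n_records=50, thesaurus=mesh)
            for q in queries:
                assert retrieve(q, corpus, mesh) == naive_retrieve(q, corpus, mesh)


class TestMonotonicity:
    def test_or_grows_and_shrinks_and(self, mesh):
        rnd = random.Random(5)
        vocab = ["kidney", "renal", "lupus", "biopsy", "nephrotic"]
        for trial in range(10):
            corpus = random_corpus(rnd, n_records=40, thesaurus=mesh)
            q = random_query(rnd, vocab, thesaurus=mesh)
            extra = TermLeaf("text", rnd.choice(vocab), "tw")
            base = retrieve(q, corpus, mesh)
            ored = retrieve(Query(BooleanNode("OR", (q.root, extra)), "pubmed"),
                            corpus, mesh)
            anded = retrieve(Query(BooleanNode("AND", (q.root, extra)), "pubmed"),
                             corpus, mesh)
            assert base <= ored
            assert anded <= base

    def test_explosion_never_shrinks_retrieval(self, mesh):
        rnd = random.Random(6)
        for trial in range(10):
            corpus = random_corpus(rnd, n_records=50, thesaurus=mesh)
            for name in ("Kidney Diseases", "Glomerulonephritis", "Vasculitis"):
                noexp = TermLeaf(kind="descriptor", surface=name, field="mh")
                exp = dataclasses.replace(noexp, explode=True)
                assert retrieve(Query(noexp, "pubmed"), corpus, mesh) <= retrieve(
                    Query(exp, "pubmed"), corpus, mesh
                )

    def test_truncation_never_shrinks_retrieval(self, mesh):
        rnd = random.Random(7)
        for trial in range(10):
            corpus = random_corpus(rnd, n_records=50, thesaurus=mesh)
            for word in ("nephro", "glomerul", "kidney"):
                plain = TermLeaf("text", word, "tw")
                trunc = dataclasses.replace(plain, truncated=True)
                assert retrieve(Query(plain, "pubmed"), corpus, mesh) <= retrieve(
                    Query(trunc, "pubmed"), corpus, mesh
                )


class TestDialectParity:
    PAIRS = [
        ("nephropath*[tw]", "nephropath$.mp"),
        ("nephrotic[tw]", "nephrotic.mp"),
        ("kidney biopsy[tiab]", "kidney biopsy.tw"),
        ("glomerulopath*[tiab]", "glomerulopath$.tw"),
        ('"Kidney Glomerulus"[majr:noexp]', "*Kidney Glomerulus/"),
        ('"Purpura, Schoenlein-Henoch"[mh:noexp]', "Purpura, Schoenlein-Henoch/"),
    ]

    def test_paired_terms_retrieve_identically(self, mesh):
        """Same concept, different syntax: the PubMed and Ovid Medline filter
        atoms should retrieve the same records — consistent with the two
        published filters printing identical performance."""
        rnd = random.Random(9)
        for trial in range(10):
            corpus = random_corpus(rnd, n_records=60, thesaurus=mesh)
            for pm, ov in self.PAIRS:
                assert retrieve(parse(pm, "pubmed"), corpus, mesh) == retrieve(
                    parse(ov, "ovid_medline"), corpus, mesh
                )
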