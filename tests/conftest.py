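import random

import pytest

from filtercraft.corpus import CitationRecord, IndexTerm, LabeledCorpus
from filtercraft.thesaurus import toy_emtree, toy_mesh


@pytest.fixture(scope="session")
def mesh():
    return toy_mesh()


@pytest.fixture(scope="session")
def emtree():
    return toy_emtree()


@pytest.fixture
def rng():
    return random.Random(20121206)


def make_record(uid="r1", title="a title", **kw):
    defaults = dict(journal_id="J1", pub_year=2005, abstract="")
    defaults.update(kw)
    return CitationRecord(uid=uid, title=title, **defaults)


@pytest.fixture
def tiny_corpus():
    """Ten relevant / hundred irrelevant records; the token 'marker' occurs
    in 9 of 10 relevant and 5 of 100 irrelevant records."""
    records, labels = [], {}
    for i in range(10):
        title = "marker study" if i < 9 else "unrelated study"
        records.append(make_record(uid=f"rel{i}", title=title, journal_id=f"J{i % 3}"))
        labels[f"rel{i}"] = True
    for i in range(100):
        title = "marker noise" if i < 5 else "plain noise"
        records.append(make_record(uid=f"irr{i}", title=title, journal_id=f"J{i % 3}"))
        labels[f"irr{i}"] = False
    return LabeledCorpus(records, labels)
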