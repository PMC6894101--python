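import dataclasses

import pytest

import kgfuse as kf


@pytest.fixture
def tiny_corpus():
    """Four hand-checkable documents over two classes.

    Document frequencies: a=4, b=1, c=2, d=1 -> idf(a)=1.0,
    idf(b)=idf(d)=ln4+1, idf(c)=ln2+1.
    """
    return kf.preprocess_corpus(
        [
            ("d1", "a a b", "flu"),
            ("d2", "a c", "flu"),
            ("d3", "a c", "cold"),
            ("d4", "a d", "cold"),
        ]
    )


@pytest.fixture
def tiny_store():
    """Three entities: one medical, one alias-colliding song, one drug."""
    entities = (
        kf.KGEntity(
            entity_id="E1",
            canonical_name="insomnia",
            aliases=frozenset({"insomnia", "sleeplessness"}),
            categories=frozenset({"disease"}),
            attributes={"symptom": "headache dizziness"},
            related_entities=frozenset({"aspirin"}),
        ),
        kf.KGEntity(
            entity_id="E2",
            canonical_name="insomnia",
            aliases=frozenset({"insomnia"}),
            categories=frozenset({"music", "song"}),
            attributes={"album": "night tunes"},
            related_entities=frozenset(),
        ),
        kf.KGEntity(
            entity_id="E3",
            canonical_name="antiarrhythmics",
            aliases=frozenset({"antiarrhythmics"}),
            categories=frozenset({"medicine"}),
            attributes={"indication": "heart atrium arrhythmia severe syndrome"},
            related_entities=frozenset(),
        ),
    )
    return kf.KnowledgeGraphStore(entities)


@pytest.fixture(scope="session")
def small_benchmark():
    """A quick-to-train synthetic benchmark used across test modules."""
    spec = kf.SyntheticSpec(
        n_classes=20,
        n_docs=1200,
        background_vocab=400,
        n_irrelevant_entities=5,
        seed=3,
    )
    corpus, store, ground_truth = kf.generate_benchmark(spec)
    return spec, corpus, store, ground_truth


@pytest.fixture(scope="session")
def default_benchmark_full_coverage():
    """The default study-scale benchmark with a fully covering KG."""
    spec = dataclasses.replace(kf.SyntheticSpec(), kg_coverage=1.0, seed=2026)
    corpus, store, ground_truth = kf.generate_benchmark(spec)
    return spec, corpus, store, ground_truth
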