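"""Link disease classes to knowledge-graph entities and harvest K1/K2.

Shows the two linking routes on a small hand-built graph: an ambiguous
name resolved by the medical-category filter (matched entity), and a
class absent from the graph that falls back to the entity with the
highest content-word overlap (surrogate entity).
"""

import kgfuse as kf

MEDICAL = {"disease", "medicine"}

store = kf.KnowledgeGraphStore((
    kf.KGEntity("E1", "insomnia", frozenset({"insomnia", "sleeplessness"}),
                frozenset({"disease"}),
                {"symptom": "headache dizziness fatigue"},
                frozenset({"melatonin"})),
    kf.KGEntity("E2", "insomnia", frozenset({"insomnia"}),
                frozenset({"music"}), {"album": "night tunes"}, frozenset()),
    kf.KGEntity("E3", "antiarrhythmics", frozenset({"antiarrhythmics"}),
                frozenset({"medicine"}),
                {"indication": "heart atrium arrhythmia severe syndrome"},
                frozenset()),
))

# 'insomnia' names both a disease and a song; the category filter keeps
# the medical entity.
print("matched entity for 'insomnia':",
      kf.resolve_matched_entity("insomnia", store, MEDICAL))

# A class with no alias match: link by overlap with its high-idf profile.
corpus = kf.preprocess_corpus([
    ("d1", "severe heart arrhythmia and racing atrium", "complex heart disease"),
    ("d2", "atrium flutter heart syndrome", "complex heart disease"),
    ("d3", "cannot sleep headache at night", "insomnia"),
])
emap, kfs = kf.assemble_knowledge_features(
    corpus, store, MEDICAL, specificity_fraction=0.4
)
eid, kind = emap.mapping["complex heart disease"]
print(f"'complex heart disease' -> {kind} entity {eid} "
      f"({store.get(eid).canonical_name})")
print("K1 (matched-entity words):      ", sorted(kfs.k1))
print("K2 (surrogate, class-attested): ", sorted(kfs.k2))
print("K = K1 u K2 has", len(kfs.k), "knowledge terms")
# K1 may contain words absent from the training vocabulary (e.g.
# 'melatonin'); K2 is always a subset of it.
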