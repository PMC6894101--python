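import pytest
from hypothesis import given, settings, strategies as st

import kgfuse as kf
from kgfuse.kg import specificity_cap


MEDICAL = frozenset({"disease", "medicine", "symptom"})


class TestResolveMatchedEntity:
    def test_category_filter_disambiguates_song_from_disease(self, tiny_store):
        # "insomnia" hits both a health entity and a song entity; the
        # category whitelist must keep the health one.
        assert kf.resolve_matched_entity("insomnia", tiny_store, MEDICAL) == "E1"

    def test_alias_and_width_normalization(self, tiny_store):
        assert kf.resolve_matched_entity("Sleeplessness", tiny_store, MEDICAL) == "E1"

    def test_no_alias_hit_returns_none(self, tiny_store):
        assert kf.resolve_matched_entity("nonexistent", tiny_store, MEDICAL) is None

    def test_medical_hit_without_ambiguity(self, tiny_store):
        assert (
            kf.resolve_matched_entity("antiarrhythmics", tiny_store, MEDICAL) == "E3"
        )

    def test_empty_name_rejected(self, tiny_store):
        with pytest.raises(ValueError):
            kf.resolve_matched_entity("  ", tiny_store, MEDICAL)


class TestDiseaseProfile:
    def _docs(self, texts, label="c"):
        return kf.preprocess_corpus(
            [(f"d{i}", t, label) for i, t in enumerate(texts)]
        ).documents

    def test_argmax_by_idf(self):
        docs = self._docs(["rareterm common"])
        idf = {"rareterm": 3.0, "common": 1.0}
        assert kf.build_disease_profile("c", docs, idf, top_n=1) == {"rareterm"}

    def test_saturation_returns_all_words(self):
        docs = self._docs(["w1 w2 w3"])
        idf = {"w1": 1.0, "w2": 2.0, "w3": 3.0}
        assert kf.build_disease_profile("c", docs, idf, top_n=50) == {
            "w1", "w2", "w3",
        }

    def test_tie_broken_by_in_class_count(self):
        # equal idf: the word occurring 5 times outranks the one with 2
        docs = self._docs(["x x x y y", "x x y"])
        idf = {"x": 2.0, "y": 2.0}
        assert kf.build_disease_profile("c", docs, idf, top_n=1) == {"x"}

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            kf.build_disease_profile("c", [], {"x": 1.0})


class TestSurrogateSelection:
    def test_highest_overlap_wins(self, tiny_store):
        # mirrors linking a heart disease's profile to a heart-drug entity
        profile = {"heart", "atrium", "arrhythmia"}
        assert kf.select_surrogate_entity(profile, tiny_store) == "E3"

    def test_tie_broken_lexicographically_and_order_invariant(self):
        def entity(eid, words):
            return kf.KGEntity(
                entity_id=eid,
                canonical_name=eid,
                aliases=frozenset({eid}),
                categories=frozenset({"disease"}),
                attributes={"a": " ".join(words)},
                related_entities=frozenset(),
            )

        e1 = entity("A2", ["heart", "pain"])
        e2 = entity("A1", ["heart", "ache"])
        for order in ([e1, e2], [e2, e1]):
            store = kf.KnowledgeGraphStore(tuple(order))
            assert kf.select_surrogate_entity({"heart"}, store) == "A1"

    def test_empty_store_flagged_none(self):
        store = kf.KnowledgeGraphStore(())
        assert kf.select_surrogate_entity({"heart"}, store) is None


class TestK1:
    def test_attributes_and_related_names(self, tiny_store):
        k1, per = kf.extract_k1({"insomnia": "E1"}, tiny_store)
        assert k1 == {"headache", "dizziness", "aspirin"}
        assert per["insomnia"] == k1

    def test_no_matched_diseases_empty(self, tiny_store):
        k1, per = kf.extract_k1({}, tiny_store)
        assert k1 == frozenset()

    def test_set_semantics_across_entities(self, tiny_store):
        k1, _ = kf.extract_k1(
            {"insomnia": "E1", "heart problem": "E3"}, tiny_store
        )
        assert k1 == {
            "headache", "dizziness", "aspirin",
            "heart", "atrium", "arrhythmia", "severe", "syndrome",
        }

    def test_dangling_entity_rejected_naming_id(self, tiny_store):
        with pytest.raises(KeyError, match="E999"):
            kf.extract_k1({"x": "E999"}, tiny_store)


class TestK2:
    def _make_store(self, n_filler, shared_word_entities=1):
        """A store where 'heart' appears in `shared_word_entities` entities
        and 'ubiquitous' appears in every entity."""
        entities = [
            kf.KGEntity(
                entity_id="T0",
                canonical_name="target",
                aliases=frozenset({"target"}),
                categories=frozenset({"medicine"}),
                attributes={"a": "heart valve ubiquitous"},
                related_entities=frozenset(),
            )
        ]
        for i in range(1, n_filler + 1):
            words = "ubiquitous"
            if i < shared_word_entities:
                words += " heart"
            entities.append(
                kf.KGEntity(
                    entity_id=f"F{i:03d}",
                    canonical_name=f"filler{i}",
                    aliases=frozenset({f"filler{i}"}),
                    categories=frozenset({"disease"}),
                    attributes={"a": words},
                    related_entities=frozenset(),
                )
            )
        return kf.KnowledgeGraphStore(tuple(entities))

    def _class_docs(self):
        return kf.preprocess_corpus(
            [("d0", "heart pain ubiquitous", "c")]
        ).documents

    def test_specificity_cap_formula(self):
        assert specificity_cap(10000, 0.0001) == 1
        assert specificity_cap(50, 0.0001) == 1      # floor clipped to 1
        assert specificity_cap(10000, 0.001) == 10

    def test_specific_class_attested_word_included(self):
        store = self._make_store(n_filler=30)
        k2 = kf.extract_k2("c", "T0", self._class_docs(), store, 0.05)
        # cap = max(1, floor(0.05*31)) = 1: 'heart' (df 1) passes,
        # 'ubiquitous' (df 31) fails, 'valve' not in class docs fails.
        assert k2 == {"heart"}

    def test_word_in_too_many_entities_excluded(self):
        store = self._make_store(n_filler=30, shared_word_entities=6)
        k2 = kf.extract_k2("c", "T0", self._class_docs(), store, 0.05)
        assert "heart" not in k2

    def test_k2_subset_of_class_vocabulary(self):
        store = self._make_store(n_filler=5)
        docs = self._class_docs()
        k2 = kf.extract_k2("c", "T0", docs, store, 0.9)
        vocab = set().union(*(d.token_set for d in docs))
        assert k2 <= vocab

    @settings(deadline=None, max_examples=20)
    @given(
        frac_lo=st.floats(0.001, 0.5),
        frac_hi=st.floats(0.5, 1.0),
    )
    def test_specificity_monotonicity(self, frac_lo, frac_hi):
        store = self._make_store(n_filler=20, shared_word_entities=5)
        docs = self._class_docs()
        k_lo = kf.extract_k2("c", "T0", docs, store, frac_lo)
        k_hi = kf.extract_k2("c", "T0", docs, store, frac_hi)
        assert k_lo <= k_hi


class TestWordEntityDf:
    def test_matches_bruteforce_recount(self, small_benchmark):
        _, _, store, _ = small_benchmark
        from collections import Counter

        brute = Counter()
        for e in store.entities:
            brute.update(store.content_words(e.entity_id))
        assert store.word_entity_df == brute
        assert all(v <= len(store) for v in store.word_entity_df.values())


class TestAssemble:
    def test_full_coverage_all_matched_k2_empty(self, small_benchmark):
        import dataclasses

        spec, _, _, _ = small_benchmark
        spec_full = dataclasses.replace(spec, kg_coverage=1.0)
        corpus, store, _ = kf.generate_benchmark(spec_full)
        split = kf.per_class_split(corpus, 0.8, seed=0)
        emap, kfs = kf.assemble_knowledge_features(
            split.train, store, MEDICAL
        )
        kinds = {k for _, k in emap.mapping.values()}
        assert kinds == {"matched"}
        assert kfs.k2 == frozenset()
        assert kfs.k == kfs.k1

    def test_zero_coverage_all_surrogate_k1_empty(self, small_benchmark):
        import dataclasses

        spec, _, _, _ = small_benchmark
        spec_zero = dataclasses.replace(spec, kg_coverage=0.0)
        corpus, store, _ = kf.generate_benchmark(spec_zero)
        split = kf.per_class_split(corpus, 0.8, seed=0)
        emap, kfs = kf.assemble_knowledge_features(split.train, store, MEDICAL)
        kinds = {k for _, k in emap.mapping.values()}
        assert kinds == {"surrogate"}
        assert kfs.k1 == frozenset()

    def test_mixed_coverage_both_kinds_and_union(self, small_benchmark):
        _, corpus, store, _ = small_benchmark
        split = kf.per_class_split(corpus, 0.8, seed=0)
        emap, kfs = kf.assemble_knowledge_features(split.train, store, MEDICAL)
        kinds = {k for _, k in emap.mapping.values()}
        assert kinds == {"matched", "surrogate"}
        assert kfs.k == kfs.k1 | kfs.k2

    def test_k2_contained_in_training_vocabulary(self, small_benchmark):
        _, corpus, store, _ = small_benchmark
        split = kf.per_class_split(corpus, 0.8, seed=1)
        _, kfs = kf.assemble_knowledge_features(split.train, store, MEDICAL)
        vocab = set()
        for d in split.train:
            vocab |= d.token_set
        assert kfs.k2 <= vocab


class TestKGSnapshotIO:
    def test_roundtrip(self, tiny_store, tmp_path):
        path = tmp_path / "kg.json"
        kf.save_kg_json(tiny_store, path)
        again = kf.load_kg_json(path)
        assert len(again) == len(tiny_store)
        assert again.alias_index == tiny_store.alias_index
        assert again.word_entity_df == tiny_store.word_entity_df

    def test_invalid_shape_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('[{"name": "missing id"}]')
        with pytest.raises(ValueError, match="id"):
            kf.load_kg_json(path)
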