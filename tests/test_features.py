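import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

import kgfuse as kf
from kgfuse import features as F


@pytest.fixture
def ab_space():
    """V = {a, b}, N = 4, df(a) = 4, df(b) = 1, K = {b}."""
    corpus = kf.preprocess_corpus(
        [("d1", "a a b", "x"), ("d2", "a", "x"), ("d3", "a", "y"), ("d4", "a", "y")]
    )
    return corpus, kf.fit_feature_space(corpus, K={"b"})


def _doc(text, label="x"):
    return kf.preprocess_corpus([("q", text, label)]).documents[0]


class TestFitFeatureSpace:
    def test_idf_formula(self, ab_space):
        _, space = ab_space
        idf = dict(zip(space.vocabulary, space.idf))
        assert idf["a"] == pytest.approx(1.0)                 # ln(4/4)+1
        assert idf["b"] == pytest.approx(math.log(4) + 1)     # ~2.3863

    def test_idf_strictly_decreasing_in_df(self, small_benchmark):
        _, corpus, _, _ = small_benchmark
        space = kf.fit_feature_space(corpus)
        pairs = sorted(zip((space.df[t] for t in space.vocabulary), space.idf))
        for (df1, i1), (df2, i2) in zip(pairs, pairs[1:]):
            if df1 < df2:
                assert i1 > i2

    def test_vk_is_intersection_in_vocab_order(self, ab_space):
        corpus, _ = ab_space
        space = kf.fit_feature_space(corpus, K={"b", "zzz_not_in_v"})
        assert space.vk == ("b",)

    def test_disjoint_k_gives_empty_vk(self, ab_space):
        corpus, _ = ab_space
        space = kf.fit_feature_space(corpus, K={"zzz"})
        assert space.vk == ()
        fused = kf.transform_early_fusion(_doc("a a b"), space)
        assert fused.knowledge_segment.size == 0

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            kf.fit_feature_space(kf.LabeledCorpus(()))


class TestTransforms:
    def test_bow_hand_computed(self, ab_space):
        # counts (2, 1) -> weights (2.0, 2.3863) -> L2 length 3.1136
        _, space = ab_space
        vec = kf.transform_bow(_doc("a a b"), space)
        assert vec == pytest.approx([0.6423, 0.7664], abs=1e-4)
        assert np.linalg.norm(vec) == pytest.approx(1.0)

    def test_oov_only_doc_is_zero_vector(self, ab_space):
        _, space = ab_space
        assert not kf.transform_bow(_doc("zzz qqq"), space).any()

    def test_early_fusion_hand_computed(self, ab_space):
        _, space = ab_space
        fused = kf.transform_early_fusion(_doc("a a b"), space)
        assert fused.concatenated == pytest.approx(
            [0.6423, 0.7664, 1.0], abs=1e-4
        )

    def test_no_vk_terms_gives_zero_knowledge_segment(self, ab_space):
        _, space = ab_space
        fused = kf.transform_early_fusion(_doc("a a"), space)
        assert not fused.knowledge_segment.any()
        assert np.linalg.norm(fused.bow_segment) == pytest.approx(1.0)

    def test_shared_word_emphasized_in_knowledge_segment(self, ab_space):
        # the knowledge segment is shorter pre-normalization, so the
        # shared word's value there strictly exceeds its bow value
        _, space = ab_space
        fused = kf.transform_early_fusion(_doc("a a b"), space)
        i_b = space.index["b"]
        j_b = space.vk_index["b"]
        assert fused.knowledge_segment[j_b] > fused.bow_segment[i_b]

    def test_transforms_are_pure(self, ab_space):
        _, space = ab_space
        d = _doc("a b a")
        v1, v2 = kf.transform_bow(d, space), kf.transform_bow(d, space)
        assert np.array_equal(v1, v2)
        f1, f2 = kf.transform_early_fusion(d, space), kf.transform_early_fusion(d, space)
        assert np.array_equal(f1.concatenated, f2.concatenated)

    def test_matches_sklearn_tfidf(self, small_benchmark):
        # independent route: sklearn's raw-tf, non-smoothed-idf variant
        from sklearn.feature_extraction.text import TfidfVectorizer

        _, corpus, _, _ = small_benchmark
        docs = corpus.documents[:200]
        sub = kf.LabeledCorpus(docs)
        space = kf.fit_feature_space(sub)
        vec = TfidfVectorizer(
            analyzer=lambda d: list(d.tokens), smooth_idf=False, norm="l2",
            sublinear_tf=False,
        )
        X_ref = vec.fit_transform(docs)
        X = F.bow_matrix(docs, space)
        ref_terms = vec.get_feature_names_out().tolist()
        perm = [ref_terms.index(t) for t in space.vocabulary]
        assert np.allclose(X.toarray(), X_ref.toarray()[:, perm], atol=1e-12)


class TestPseudoCount:
    def test_k_zero_is_plain_bow(self, ab_space):
        _, space = ab_space
        d = _doc("a a b")
        assert np.array_equal(
            kf.transform_pseudo_count(d, space, 0), kf.transform_bow(d, space)
        )

    def test_k_one_adds_to_present_vk_terms(self, ab_space):
        _, space = ab_space
        vec = kf.transform_pseudo_count(_doc("a a b"), space, 1)
        # counts become (2, 1+1); weights (2.0, 2*2.3863)
        w = np.array([2.0, 2 * (math.log(4) + 1)])
        assert vec == pytest.approx(w / np.linalg.norm(w))

    def test_absent_vk_term_unchanged_by_any_k(self, ab_space):
        _, space = ab_space
        d = _doc("a a")
        assert np.array_equal(
            kf.transform_pseudo_count(d, space, 100), kf.transform_bow(d, space)
        )

    def test_negative_k_rejected(self, ab_space):
        _, space = ab_space
        with pytest.raises(ValueError):
            kf.transform_pseudo_count(_doc("a"), space, -1)


class TestChi2:
    def test_hand_computed_two_by_two(self):
        # term in both class-1 docs, absent from both class-2 docs:
        # table [[2,0],[0,2]], chi2 = N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 4
        corpus = kf.preprocess_corpus(
            [("1", "t u", "c1"), ("2", "t u", "c1"),
             ("3", "u", "c2"), ("4", "u", "c2")]
        )
        space = kf.fit_feature_space(corpus)
        selected = kf.chi2_feature_selection(corpus, space, 2)
        assert selected[0] == "t"
        # recompute the statistic directly for 't'
        table = np.array([[2, 0], [0, 2]])
        ref = chi2_contingency(table, correction=False).statistic
        assert ref == pytest.approx(4.0)

    def test_term_in_every_document_scores_zero(self):
        corpus = kf.preprocess_corpus(
            [("1", "u t", "c1"), ("2", "u", "c2")]
        )
        space = kf.fit_feature_space(corpus)
        # 'u' is everywhere -> no association; 't' separates the classes
        assert kf.chi2_feature_selection(corpus, space, 2) == ("t", "u")

    def test_m_equals_vocab_returns_everything(self):
        corpus = kf.preprocess_corpus([("1", "a b", "c1"), ("2", "c", "c2")])
        space = kf.fit_feature_space(corpus)
        assert set(kf.chi2_feature_selection(corpus, space, 3)) == {"a", "b", "c"}

    def test_single_class_rejected(self):
        corpus = kf.preprocess_corpus([("1", "a", "c1"), ("2", "b", "c1")])
        space = kf.fit_feature_space(corpus)
        with pytest.raises(ValueError):
            kf.chi2_feature_selection(corpus, space, 1)

    @settings(deadline=None, max_examples=20)
    @given(st.data())
    def test_agrees_with_contingency_table_oracle(self, data):
        """Scores match scipy's chi-square on the 2xC presence table for
        every term, on random corpora of <= 20 documents."""
        n_docs = data.draw(st.integers(4, 20))
        n_classes = data.draw(st.integers(2, 4))
        vocab = ["w0", "w1", "w2", "w3", "w4"]
        records = []
        for i in range(n_docs):
            words = data.draw(
                st.lists(st.sampled_from(vocab), min_size=1, max_size=5)
            )
            label = f"c{i % n_classes}"
            records.append((f"d{i}", " ".join(words), label))
        corpus = kf.preprocess_corpus(records)
        space = kf.fit_feature_space(corpus)
        scores = F.chi2_scores(corpus, space)

        labels = sorted(corpus.labels)
        sizes = np.array([corpus.class_counts[l] for l in labels], dtype=float)

        def oracle(term):
            present = np.array(
                [
                    sum(1 for d in corpus if d.label == l and term in d.token_set)
                    for l in labels
                ],
                dtype=float,
            )
            if present.sum() in (0, len(corpus)):
                return 0.0
            table = np.vstack([present, sizes - present])
            return float(chi2_contingency(table, correction=False).statistic)

        expected = np.array([oracle(t) for t in space.vocabulary])
        assert np.allclose(scores, expected, atol=1e-9)


class TestBatchMatrixTransforms:
    def test_rows_match_per_document_functions(self, small_benchmark):
        _, corpus, store, _ = small_benchmark
        split = kf.per_class_split(corpus, 0.8, seed=0)
        _, kfs = kf.assemble_knowledge_features(
            split.train, store, kf.MEDICAL_CATEGORIES
        )
        space = kf.fit_feature_space(split.train, kfs.k)
        docs = split.test.documents[:30]
        X = F.fused_matrix(docs, space).toarray()
        for i, d in enumerate(docs):
            assert np.allclose(
                X[i], kf.transform_early_fusion(d, space).concatenated, atol=1e-12
            )
        P = F.pseudo_count_matrix(docs, space, 1).toarray()
        for i, d in enumerate(docs):
            assert np.allclose(
                P[i], kf.transform_pseudo_count(d, space, 1), atol=1e-12
            )

    def test_mtx_roundtrip(self, tmp_path, ab_space):
        corpus, space = ab_space
        X = F.bow_matrix(corpus.documents, space)
        F.save_feature_matrix(tmp_path / "m", X, space.vocabulary)
        X2, terms = F.load_feature_matrix(tmp_path / "m")
        assert terms == space.vocabulary
        assert np.allclose(X.toarray(), X2.toarray())


class TestFusedNormGeometry:
    def test_fused_norm_between_one_and_sqrt_two(self, small_benchmark):
        _, corpus, store, _ = small_benchmark
        split = kf.per_class_split(corpus, 0.8, seed=0)
        _, kfs = kf.assemble_knowledge_features(
            split.train, store, kf.MEDICAL_CATEGORIES
        )
        space = kf.fit_feature_space(split.train, kfs.k)
        checked = 0
        for d in split.test.documents[:100]:
            fused = kf.transform_early_fusion(d, space)
            bn = np.linalg.norm(fused.bow_segment)
            kn = np.linalg.norm(fused.knowledge_segment)
            if bn > 0 and kn > 0:
                norm = np.linalg.norm(fused.concatenated)
                assert 1.0 < norm <= math.sqrt(2) + 1e-12
                checked += 1
        assert checked > 10
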