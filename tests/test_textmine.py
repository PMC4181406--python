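"""Vocabulary filtering, TF-IDF weighting and the dictionary matcher."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from netphen.errors import ConfigurationError, DataIntegrityError
from netphen.textmine import (DocumentAnnotation, TermRecord, TermVector,
                              VocabularyFilter, apply_filter,
                              inverse_document_frequencies,
                              naive_concept_map, tfidf_weight,
                              weight_document)


class TestApplyFilter:
    def test_by_vocab_keeps_only_matching_terms(self, term_table):
        doc = DocumentAnnotation("d", {"t1": 2, "t2": 1})
        out = apply_filter([doc], term_table,
                           VocabularyFilter.by_vocab("MeSH"))
        assert out[0].counts == {"t1": 2}

    def test_semantic_type_exclusion_can_empty_a_document(self, term_table):
        # a term typed as an administrative activity is dropped by a
        # phenotype-relevant semantic-type whitelist
        doc = DocumentAnnotation("d", {"t5": 2})
        filt = VocabularyFilter.by_semantic_types(
            {"Disease or Syndrome", "Cell Function"})
        out = apply_filter([doc], term_table, filt)
        assert out[0].counts == {}
        assert out[0].doc_id == "d"  # retained, not dropped

    def test_allowing_everything_is_identity(self, term_table, small_docs):
        all_types = {r.semantic_type for r in term_table.values()}
        out = apply_filter(small_docs, term_table,
                           VocabularyFilter.by_semantic_types(all_types))
        assert [a.counts for a in out] == [a.counts for a in small_docs]

    def test_unknown_vocabulary_is_configuration_error(self, term_table,
                                                       small_docs):
        with pytest.raises(ConfigurationError, match="SNOMED"):
            apply_filter(small_docs, term_table,
                         VocabularyFilter.by_vocab("SNOMED"))

    def test_missing_term_record_names_the_term(self, term_table):
        doc = DocumentAnnotation("d", {"t99": 1})
        with pytest.raises(DataIntegrityError, match="t99"):
            apply_filter([doc], term_table,
                         VocabularyFilter.by_vocab("MeSH"))

    def test_idempotent(self, term_table, small_docs):
        filt = VocabularyFilter.by_vocab("MeSH")
        once = apply_filter(small_docs, term_table, filt)
        twice = apply_filter(once, term_table, filt)
        assert [a.counts for a in once] == [a.counts for a in twice]

    def test_filter_constructor_rejects_mixed_modes(self):
        with pytest.raises(ConfigurationError):
            VocabularyFilter(mode=VocabularyFilter.by_vocab("MeSH").mode)


class TestTfidf:
    def test_ubiquitous_term_gets_zero_weight_everywhere(self):
        docs = [DocumentAnnotation("d1", {"a": 1}),
                DocumentAnnotation("d2", {"a": 2, "b": 1})]
        vectors = tfidf_weight(docs)
        assert all("a" not in v.weights for v in vectors)

    def test_hand_computed_weight(self):
        # d2 = {a:1, b:1}: tf(b) = 1/2, df(b) = 1 of 2 docs, idf = ln 2
        docs = [DocumentAnnotation("d1", {"a": 1}),
                DocumentAnnotation("d2", {"a": 1, "b": 1})]
        v2 = tfidf_weight(docs)[1]
        assert v2.weights["b"] == pytest.approx(0.5 * math.log(2))

    def test_unique_single_term_document_weight_is_log_e(self):
        docs = [DocumentAnnotation("d1", {"u": 3}),
                DocumentAnnotation("d2", {"x": 1}),
                DocumentAnnotation("d3", {"x": 2})]
        v1 = tfidf_weight(docs)[0]
        assert v1.weights["u"] == pytest.approx(math.log(3))

    def test_empty_document_yields_zero_vector(self):
        docs = [DocumentAnnotation("d1", {}),
                DocumentAnnotation("d2", {"x": 1})]
        assert tfidf_weight(docs)[0].weights == {}

    def test_invariant_to_document_order(self, small_docs):
        fwd = {v.doc_id: v.weights for v in tfidf_weight(small_docs)}
        rev = {v.doc_id: v.weights for v in tfidf_weight(small_docs[::-1])}
        assert fwd == rev

    def test_filter_then_weight_equals_weight_on_filtered_cohort(
            self, term_table, small_docs):
        # df must be recounted on the filtered cohort, not inherited
        filt = VocabularyFilter.by_vocab("MeSH")
        filtered = apply_filter(small_docs, term_table, filt)
        direct = tfidf_weight(filtered)
        recomputed = tfidf_weight(
            apply_filter(filtered, term_table, filt))
        assert [v.weights for v in direct] == [v.weights for v in recomputed]

    def test_external_idf_places_document_in_cohort_space(self, small_docs):
        idf = inverse_document_frequencies(small_docs)
        disease = DocumentAnnotation("dis", {"t2": 1, "tX": 4})
        vec = weight_document(disease, idf)
        # tX never seen in the cohort: dropped; t2 weighted by cohort idf
        assert set(vec.weights) == {"t2"}
        assert vec.weights["t2"] == pytest.approx((1 / 5) * idf["t2"])

    @given(counts=st.lists(
        st.dictionaries(st.sampled_from("abcdef"),
                        st.integers(min_value=1, max_value=9), min_size=1),
        min_size=2, max_size=8))
    def test_weights_nonnegative_and_df_e_terms_absent(self, counts):
        docs = [DocumentAnnotation(f"d{i}", c) for i, c in enumerate(counts)]
        everywhere = set.intersection(*(set(c) for c in counts))
        for v in tfidf_weight(docs):
            assert all(w > 0 for w in v.weights.values())
            assert not everywhere & set(v.weights)


class TestNaiveConceptMap:
    def test_longest_match_wins(self):
        ann = naive_concept_map(
            "parkinson disease tremor",
            {"parkinson disease": "T1", "tremor": "T2", "disease": "T3"})
        assert ann.counts == {"T1": 1, "T2": 1}

    def test_repeated_matches_are_counted(self):
        ann = naive_concept_map("disease disease", {"disease": "T1"})
        assert ann.counts == {"T1": 2}

    def test_empty_text_and_case_insensitivity(self):
        assert naive_concept_map("", {"x": "T"}).counts == {}
        assert naive_concept_map("TREMOR", {"tremor": "T2"}).counts == {"T2": 1}

    def test_word_boundaries_prevent_substring_matches(self):
        assert naive_concept_map("predisease", {"disease": "T"}).counts == {}


class TestDomainTypes:
    def test_negative_count_rejected(self):
        with pytest.raises(DataIntegrityError):
            DocumentAnnotation("d", {"t": 0})

    def test_term_vector_drops_explicit_zeros(self):
        v = TermVector("d", {"a": 0.0, "b": 1.5})
        assert v.weights == {"b": 1.5}

    def test_term_record_requires_a_vocabulary(self):
        with pytest.raises(DataIntegrityError):
            TermRecord("t", frozenset(), "Disease or Syndrome")
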