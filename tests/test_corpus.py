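from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emr2vec import (
    PatientRecord,
    build_corpus,
    fit_lab_panel,
    mixture_vector,
    multi_hot,
    one_hot,
    shuffle_corpus,
    tokenize_cohort,
)
from emr2vec.corpus import CorpusError, load_corpus, save_corpus


class TestBuildCorpus:
    def test_vocabulary_and_counts(self):
        c = build_corpus([["A", "B"], ["B", "C"]])
        assert c.vocabulary == ["A", "B", "C"]
        assert c.token_counts["B"] == 2

    def test_single_token_sentence(self):
        assert build_corpus([["A"]]).vocab_size == 1

    def test_empty_input_rejected(self):
        with pytest.raises(CorpusError):
            build_corpus([])
        with pytest.raises(CorpusError):
            build_corpus([[]])

    def test_round_trip_text_format(self, tmp_path):
        c = build_corpus([["A", "B"], ["C"]])
        save_corpus(c, tmp_path / "c.txt")
        c2 = load_corpus(tmp_path / "c.txt")
        assert c2.sentences == c.sentences
        assert c2.vocabulary == c.vocabulary

    def test_synthetic_vocab_covered_by_ledger(self, small_cohort):
        """Every corpus token is a concept the generator declares."""
        spec, records, truth, ledger, schema = small_cohort
        sentences, _ = tokenize_cohort(records, schema)
        c = build_corpus(sentences)
        assert set(c.vocabulary) <= set(ledger.token)


sentences_strategy = st.lists(
    st.lists(st.sampled_from([f"t{i}" for i in range(12)]), min_size=1, max_size=10),
    min_size=1,
    max_size=20,
)


class TestShuffle:
    @given(sentences_strategy, st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=50)
    def test_conserves_multisets_and_order_of_sentences(self, sents, seed):
        c = build_corpus(sents)
        s = shuffle_corpus(c, seed)
        assert len(s.sentences) == len(c.sentences)
        for orig, shuf in zip(c.sentences, s.sentences):
            assert Counter(orig) == Counter(shuf)
        assert s.token_counts == c.token_counts

    def test_deterministic_given_seed(self):
        c = build_corpus([list("ABCDEFG")] * 5)
        assert shuffle_corpus(c, 42).sentences == shuffle_corpus(c, 42).sentences

    def test_distinct_seeds_give_distinct_corpora(self):
        c = build_corpus([list("ABCDEFGHIJ")] * 20)
        views = {tuple(map(tuple, shuffle_corpus(c, s).sentences)) for s in range(20)}
        assert len(views) == 20


class TestOneHotMultiHot:
    def test_one_hot_index(self):
        c = build_corpus([["A", "B", "C"]])
        v = one_hot("A", c)
        assert v.tolist() == [1, 0, 0]
        assert one_hot("C", c).sum() == 1

    def test_one_hot_completeness(self):
        c = build_corpus([["A", "B"], ["C"]])
        total = sum(one_hot(t, c) for t in c.vocabulary)
        assert (total == 1).all()

    def test_unknown_token_rejected(self):
        c = build_corpus([["A"]])
        with pytest.raises(CorpusError):
            one_hot("Z", c)
        with pytest.raises(CorpusError):
            multi_hot(["Z"], c)

    def test_multi_hot_popcount(self):
        c = build_corpus([["A", "B", "C", "D"]])
        assert multi_hot(["A", "C", "D"], c).sum() == 3

    def test_duplicates_collapse(self):
        c = build_corpus([["A", "B"]])
        assert multi_hot(["A", "A", "A"], c).sum() == 1

    def test_order_invariance(self):
        c = build_corpus([["A", "B", "C"]])
        assert (multi_hot(["A", "B", "C"], c) == multi_hot(["C", "A", "B"], c)).all()

    def test_disjoint_records_jaccard_one(self):
        from emr2vec import jaccard_distance

        c = build_corpus([["A", "B"], ["C", "D"]])
        a = multi_hot(["A", "B"], c)
        b = multi_hot(["C", "D"], c)
        assert jaccard_distance(a, b) == 1.0


class TestMixture:
    def _cohort(self, toy_schema):
        records = []
        for i in range(20):
            vals = {"sex": "male", "glucose": 5.0 + i * 0.1}
            if i < 17:  # wbc observed in 85% of the cohort
                vals["wbc"] = 6.0 + i * 0.2
            records.append(PatientRecord(f"p{i}", vals))
        return records

    def test_coverage_threshold_excludes_sparse_lab(self, toy_schema):
        records = self._cohort(toy_schema)
        panel = fit_lab_panel(records, toy_schema, coverage_threshold=0.90)
        assert panel.feature_ids == ["glucose"]

    def test_panel_monotone_in_threshold(self, toy_schema):
        records = self._cohort(toy_schema)
        lower = set(fit_lab_panel(records, toy_schema, 0.80).feature_ids)
        higher = set(fit_lab_panel(records, toy_schema, 0.90).feature_ids)
        assert higher <= lower

    def test_missing_panel_lab_imputed_with_median(self, toy_schema):
        records = self._cohort(toy_schema)
        panel = fit_lab_panel(records, toy_schema, 0.80, standardize=False)
        sentences, _ = tokenize_cohort(records, toy_schema)
        c = build_corpus(sentences)
        missing = records[-1]  # has no wbc value
        assert "wbc" not in missing.values
        mv = mixture_vector(missing, sentences[-1], c, panel)
        j = panel.feature_ids.index("wbc")
        assert mv.continuous_values[j] == pytest.approx(np.median([6.0 + i * 0.2 for i in range(17)]))

    def test_present_labs_pass_through_raw(self, toy_schema):
        records = self._cohort(toy_schema)
        panel = fit_lab_panel(records, toy_schema, 0.80, standardize=False)
        sentences, _ = tokenize_cohort(records, toy_schema)
        c = build_corpus(sentences)
        mv = mixture_vector(records[0], sentences[0], c, panel)
        j = panel.feature_ids.index("glucose")
        assert mv.continuous_values[j] == 5.0

    def test_empty_panel_rejected(self, toy_schema):
        records = [PatientRecord("p0", {"sex": "male"})]
        with pytest.raises(CorpusError):
            fit_lab_panel(records, toy_schema, 0.90)

    def test_discrete_block_excludes_panel_tokens(self, toy_schema):
        records = self._cohort(toy_schema)
        panel = fit_lab_panel(records, toy_schema, 0.80)
        sentences, _ = tokenize_cohort(records, toy_schema)
        c = build_corpus(sentences)
        mv = mixture_vector(records[0], sentences[0], c, panel)
        lab_indices = [
            i for i, t in enumerate(c.vocabulary)
            if t.partition("=")[0] in panel.feature_ids
        ]
        assert mv.discrete_bits[lab_indices].sum() == 0
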