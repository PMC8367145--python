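import numpy as np
import pytest

from emr2vec import (
    EmbeddingMatrix,
    TrainConfig,
    build_corpus,
    cosine_similarity,
    embed_patient,
    embed_patients,
    ensemble_embed,
    shuffle_corpus,
    train_skipgram,
)
from emr2vec.corpus import CorpusError


class TestTrainSkipgram:
    def test_cooccurrence_structure_learned(self, two_pair_corpus, small_cfg):
        emb = train_skipgram(two_pair_corpus, small_cfg)
        ab = cosine_similarity(emb.vector("A"), emb.vector("B"))
        ac = cosine_similarity(emb.vector("A"), emb.vector("C"))
        cd = cosine_similarity(emb.vector("C"), emb.vector("D"))
        cb = cosine_similarity(emb.vector("C"), emb.vector("B"))
        assert ab > ac and cd > cb

    def test_dimension_from_config(self, two_pair_corpus):
        emb = train_skipgram(two_pair_corpus, TrainConfig(dim=200, epochs=1, seed=0))
        assert emb.vectors.shape == (4, 200)

    def test_loss_decreases(self, two_pair_corpus, small_cfg):
        losses = train_skipgram(two_pair_corpus, small_cfg).provenance["epoch_losses"]
        assert losses[-1] < losses[0]

    def test_deterministic_bit_identical(self, two_pair_corpus, small_cfg):
        e1 = train_skipgram(two_pair_corpus, small_cfg)
        e2 = train_skipgram(two_pair_corpus, small_cfg)
        assert (e1.vectors == e2.vectors).all()

    def test_no_context_pairs_rejected(self, small_cfg):
        with pytest.raises(CorpusError):
            train_skipgram(build_corpus([["A"], ["B"]]), small_cfg)

    def test_min_count_drops_rare_tokens(self, small_cfg):
        from dataclasses import replace

        c = build_corpus([["A", "B"]] * 10 + [["A", "rare"]])
        emb = train_skipgram(c, replace(small_cfg, min_count=2))
        assert "rare" not in emb.vocabulary
        assert "A" in emb.vocabulary

    def test_max_window_resolves_to_longest_sentence(self):
        c = build_corpus([["A", "B"], list("ABCDE")])
        assert TrainConfig(window="max").resolve_window(c) == 5

    def test_window_max_covers_all_pairs(self):
        """With window = max sentence length, the pair set the trainer sweeps
        equals the brute-force set of all ordered within-sentence pairs."""

        def kernel_pairs(sentence, window):
            pairs = set()
            n = len(sentence)
            for t in range(n):
                lo = max(0, t - window)
                hi = min(n, t + window + 1)
                for j in range(lo, hi):
                    if j != t:
                        pairs.add((t, j))
            return pairs

        sent = list("ABCDEFG")
        window = len(sent)
        brute = {(t, j) for t in range(len(sent)) for j in range(len(sent)) if t != j}
        assert kernel_pairs(sent, window) == brute
        assert kernel_pairs(sent, 2) < brute


class TestEnsemble:
    def test_single_shuffle_equals_one_run(self, two_pair_corpus, small_cfg):
        from dataclasses import replace

        cfg = replace(small_cfg, n_shuffles=1)
        ens = ensemble_embed(two_pair_corpus, cfg)
        seed = ens.provenance["shuffle_seeds"][0]
        single = train_skipgram(shuffle_corpus(two_pair_corpus, seed), cfg)
        # shared init: the 1-run ensemble must reproduce the single run exactly
        np.testing.assert_allclose(ens.vectors, single.vectors)

    def test_averaging_reduces_variance(self, two_pair_corpus):
        """Across repeats, cos(A,B) varies no more for the ensemble mean than
        for single runs (stability property of averaging)."""
        from dataclasses import replace

        base = TrainConfig(dim=16, window=5, epochs=2, n_shuffles=4)
        ens_vals, single_vals = [], []
        for seed in range(8):
            cfg = replace(base, seed=seed)
            e = ensemble_embed(two_pair_corpus, cfg)
            ens_vals.append(cosine_similarity(e.vector("A"), e.vector("B")))
            s = train_skipgram(shuffle_corpus(two_pair_corpus, seed), cfg)
            single_vals.append(cosine_similarity(s.vector("A"), s.vector("B")))
        assert np.var(ens_vals) <= np.var(single_vals) + 1e-12

    def test_provenance_records_ensemble(self, two_pair_corpus, small_cfg):
        ens = ensemble_embed(two_pair_corpus, small_cfg)
        assert ens.provenance["ensemble_size"] == small_cfg.n_shuffles
        assert len(ens.provenance["shuffle_seeds"]) == small_cfg.n_shuffles


class TestEmbedPatient:
    def _embeddings(self):
        vocab = ["a", "b", "c"]
        vecs = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        return EmbeddingMatrix(vocab, vecs)

    def test_single_token_record(self):
        emb = self._embeddings()
        np.testing.assert_allclose(embed_patient(["a"], emb), [1.0, 0.0])

    def test_mean_of_two(self):
        emb = self._embeddings()
        np.testing.assert_allclose(embed_patient(["a", "b"], emb), [0.5, 0.5])

    def test_order_invariant(self):
        emb = self._embeddings()
        np.testing.assert_allclose(
            embed_patient(["a", "b", "c"], emb), embed_patient(["c", "a", "b"], emb)
        )

    def test_unknown_tokens_skipped_with_warning(self, caplog):
        emb = self._embeddings()
        with caplog.at_level("WARNING"):
            v = embed_patient(["a", "zz"], emb)
        np.testing.assert_allclose(v, [1.0, 0.0])
        assert any("zz" in m for m in caplog.messages)

    def test_all_unknown_rejected(self):
        with pytest.raises(CorpusError):
            embed_patient(["zz"], self._embeddings())

    def test_matrix_stacks_rows(self):
        emb = self._embeddings()
        X = embed_patients([["a"], ["b"]], emb)
        assert X.shape == (2, 2)


class TestEmbeddingIO:
    def test_text_round_trip(self, tmp_path, two_pair_corpus, small_cfg):
        emb = train_skipgram(two_pair_corpus, small_cfg)
        emb.save_text(tmp_path / "emb.txt")
        loaded = EmbeddingMatrix.load_text(tmp_path / "emb.txt")
        assert loaded.vocabulary == emb.vocabulary
        np.testing.assert_allclose(loaded.vectors, emb.vectors, rtol=1e-4)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            EmbeddingMatrix(["a"], np.array([[np.nan]]))
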