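"""Skip-gram with negative sampling (SGNS) for medical-concept corpora.

The trainer learns one d-dimensional vector per concept token by sliding a
fixed context window over each record-sentence and, for every
(target, context) pair, pushing the target's input vector toward the
context's output vector while pushing it away from ``negatives`` noise
tokens drawn from the unigram^0.75 distribution.

Records have no meaningful internal order, so correlated concepts may sit
farther apart than the window reaches. The remedy implemented by
:func:`ensemble_embed` is the shuffle ensemble: permute tokens within every
sentence, train, repeat ``n_shuffles`` times (default 20), and average each
token's vectors elementwise. All ensemble runs share the same weight
initialization — independently initialized runs would differ by arbitrary
rotations and their elementwise mean would collapse toward zero — so only
the within-sentence order varies across runs.

The optimization is plain SGD with a linearly decaying learning rate,
single-threaded and bit-deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from numba import njit

from .corpus import Corpus, CorpusError, build_corpus, shuffle_corpus

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Hyperparameters of the SGNS trainer.

    ``window`` may be an int or the string ``"max"``, which resolves to the
    longest sentence length of the corpus in use (every within-sentence pair
    then becomes a training pair).
    """

    dim: int = 200
    window: Union[int, str] = 5
    epochs: int = 5
    negatives: int = 5
    learning_rate: tuple[float, float] = (0.025, 0.0001)
    min_count: int = 1
    seed: int = 0
    n_shuffles: int = 20

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.window != "max" and int(self.window) < 1:
            raise ValueError("window must be >= 1 or 'max'")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")

    def resolve_window(self, corpus: Corpus) -> int:
        if self.window == "max":
            return corpus.max_sentence_length
        return int(self.window)


@dataclass
class EmbeddingMatrix:
    vocabulary: list[str]
    vectors: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocabulary):
            raise ValueError("one vector row per vocabulary token required")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite entries")
        self.index = {tok: i for i, tok in enumerate(self.vocabulary)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def vector(self, token: str) -> np.ndarray:
        if token not in self.index:
            raise KeyError(f"token not in embedding vocabulary: {token!r}")
        return self.vectors[self.index[token]]

    def save_text(self, path: str | Path) -> None:
        """Plain-text interchange format: header ``V d``, one token per line."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vocabulary)} {self.dim}\n")
            for tok, row in zip(self.vocabulary, self.vectors):
                fh.write(tok + " " + " ".join(f"{x:.6g}" for x in row) + "\n")

    @classmethod
    def load_text(cls, path: str | Path) -> "EmbeddingMatrix":
        with open(path) as fh:
            header = fh.readline().split()
            n, d = int(header[0]), int(header[1])
            vocab, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vocab.append(parts[0])
                rows.append(np.array(parts[1 : d + 1], dtype=np.float64))
        if len(vocab) != n:
            raise ValueError("embedding file truncated")
        return cls(vocab, np.vstack(rows))


@njit(cache=True, fastmath=True)
def _sgns_kernel(
    tokens, offsets, w_in, w_out, window, negatives, lr_start, lr_end,
    epochs, neg_cdf, seed,
):  # pragma: no cover - exercised through train_skipgram
    np.random.seed(seed)
    dim = w_in.shape[1]
    n_sent = offsets.shape[0] - 1
    total_pairs = 0
    for s in range(n_sent):
        length = offsets[s + 1] - offsets[s]
        for t in range(length):
            lo = t - window if t - window > 0 else 0
            hi = t + window + 1 if t + window + 1 < length else length
            total_pairs += hi - lo - 1
    total = total_pairs * epochs
    losses = np.zeros(epochs)
    grad = np.empty(dim, dtype=np.float32)
    seen = 0
    for epoch in range(epochs):
        loss = 0.0
        npairs = 0
        for s in range(n_sent):
            start = offsets[s]
            length = offsets[s + 1] - start
            for t in range(length):
                center = tokens[start + t]
                lo = t - window if t - window > 0 else 0
                hi = t + window + 1 if t + window + 1 < length else length
                for j in range(lo, hi):
                    if j == t:
                        continue
                    context = tokens[start + j]
                    lr = lr_start + (lr_end - lr_start) * (seen / total)
                    seen += 1
                    npairs += 1
                    for k in range(dim):
                        grad[k] = 0.0
                    # positive pair + sampled negatives
                    for ni in range(negatives + 1):
                        if ni == 0:
                            target = context
                            label = 1.0
                        else:
                            r = np.random.random()
                            target = np.searchsorted(neg_cdf, r)
                            if target == center:
                                continue
                            label = 0.0
                        dot = 0.0
                        for k in range(dim):
                            dot += w_in[center, k] * w_out[target, k]
                        if dot > 8.0:
                            p = 1.0
                        elif dot < -8.0:
                            p = 0.0
                        else:
                            p = 1.0 / (1.0 + math.exp(-dot))
                        if label > 0.5:
                            loss -= math.log(p + 1e-10)
                        else:
                            loss -= math.log(1.0 - p + 1e-10)
                        g = lr * (label - p)
                        for k in range(dim):
                            grad[k] += g * w_out[target, k]
                            w_out[target, k] += g * w_in[center, k]
                    for k in range(dim):
                        w_in[center, k] += grad[k]
        losses[epoch] = loss / max(npairs, 1)
    return losses


def _filtered(corpus: Corpus, min_count: int) -> Corpus:
    if min_count <= 1:
        return corpus
    keep = {t for t, c in corpus.token_counts.items() if c >= min_count}
    sents = [[t for t in s if t in keep] for s in corpus.sentences]
    sents = [s for s in sents if s]
    if not sents:
        raise CorpusError("min_count filtering removed every sentence")
    return build_corpus(sents)


def _init_weights(vocab_size: int, dim: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    w_in = ((rng.random((vocab_size, dim)) - 0.5) / dim).astype(np.float32)
    w_out = np.zeros((vocab_size, dim), dtype=np.float32)
    return w_in, w_out


def _noise_cdf(corpus: Corpus) -> np.ndarray:
    counts = np.array(
        [corpus.token_counts[t] for t in corpus.vocabulary], dtype=np.float64
    )
    probs = counts**0.75
    probs /= probs.sum()
    return np.cumsum(probs)


def train_skipgram(
    corpus: Corpus,
    config: TrainConfig,
    _init: tuple[np.ndarray, np.ndarray] | None = None,
) -> EmbeddingMatrix:
    """Train SGNS on one corpus and return the input-side vectors.

    Deterministic given ``config.seed`` (single-threaded). The returned
    matrix carries the per-epoch mean loss in ``provenance["epoch_losses"]``.
    """
    corpus = _filtered(corpus, config.min_count)
    if corpus.max_sentence_length < 2:
        raise CorpusError("no context pairs: every sentence is shorter than 2 tokens")
    window = config.resolve_window(corpus)
    if _init is None:
        w_in, w_out = _init_weights(corpus.vocab_size, config.dim, config.seed)
    else:
        w_in, w_out = _init[0].copy(), _init[1].copy()
    tokens_flat = np.concatenate(corpus.encoded())
    lengths = np.array([len(s) for s in corpus.sentences], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
    lr_start, lr_end = config.learning_rate
    losses = _sgns_kernel(
        tokens_flat, offsets, w_in, w_out, window, config.negatives,
        lr_start, lr_end, config.epochs, _noise_cdf(corpus),
        config.seed % (2**31 - 1),
    )
    return EmbeddingMatrix(
        list(corpus.vocabulary),
        w_in.astype(np.float64),
        provenance={
            "config": {
                "dim": config.dim, "window": window, "epochs": config.epochs,
                "negatives": config.negatives, "min_count": config.min_count,
                "seed": config.seed,
            },
            "epoch_losses": [float(x) for x in losses],
            "ensemble_size": 1,
        },
    )


def ensemble_embed(corpus: Corpus, config: TrainConfig) -> EmbeddingMatrix:
    """Shuffle-train ``n_shuffles`` times and average each token's vectors.

    Every run starts from the same weight initialization (seeded by
    ``config.seed``); only the within-sentence token order differs, via
    shuffle seeds derived from the master seed.
    """
    base = _filtered(corpus, config.min_count)
    init = _init_weights(base.vocab_size, config.dim, config.seed)
    shuffle_seeds = [
        int(s) % (2**31 - 1)
        for s in np.random.SeedSequence(config.seed).generate_state(config.n_shuffles)
    ]
    mean_vectors: np.ndarray | None = None
    losses = []
    for run_seed in shuffle_seeds:
        shuffled = shuffle_corpus(base, run_seed)
        emb = train_skipgram(shuffled, config, _init=init)
        losses.append(emb.provenance["epoch_losses"])
        if mean_vectors is None:
            vocab = emb.vocabulary
            mean_vectors = emb.vectors.copy()
        else:
            mean_vectors += emb.vectors
    assert mean_vectors is not None
    mean_vectors /= config.n_shuffles
    return EmbeddingMatrix(
        vocab,
        mean_vectors,
        provenance={
            "config": {
                "dim": config.dim, "window": config.resolve_window(base),
                "epochs": config.epochs, "negatives": config.negatives,
                "min_count": config.min_count, "seed": config.seed,
            },
            "ensemble_size": config.n_shuffles,
            "shuffle_seeds": shuffle_seeds,
            "epoch_losses": losses[0],
        },
    )


def embed_patient(sentence: Sequence[str], embeddings: EmbeddingMatrix) -> np.ndarray:
    """Patient vector: arithmetic mean of the record's concept vectors.

    Tokens missing from the embedding vocabulary are skipped with a warning;
    if nothing remains the record cannot be represented and an error is
    raised.
    """
    rows = []
    for tok in sentence:
        if tok in embeddings:
            rows.append(embeddings.vector(tok))
        else:
            logger.warning("token %r not in embedding vocabulary; skipped", tok)
    if not rows:
        raise CorpusError("no sentence token found in the embedding vocabulary")
    return np.mean(rows, axis=0)


def embed_patients(
    sentences: Sequence[Sequence[str]], embeddings: EmbeddingMatrix
) -> np.ndarray:
    """n_patients x d matrix of patient vectors."""
    return np.stack([embed_patient(s, embeddings) for s in sentences])
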