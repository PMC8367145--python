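"""Count-based co-occurrence embeddings: PPMI matrix factorized by SVD.

A classical, optimization-free alternative to the SGNS trainer: count
symmetric window co-occurrences, form the positive pointwise mutual
information matrix, and take a truncated SVD. Because SGNS implicitly
factorizes a shifted PMI matrix, the two methods should broadly agree on
which token pairs are similar; the package uses this route as an
independent cross-check of the trainer's similarity rankings.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.linalg import svds

from .corpus import Corpus
from .skipgram import EmbeddingMatrix


def cooccurrence_counts(corpus: Corpus, window: int) -> np.ndarray:
    """Dense symmetric co-occurrence counts within the given window."""
    V = corpus.vocab_size
    C = np.zeros((V, V), dtype=np.float64)
    for sent in corpus.encoded():
        n = len(sent)
        for t in range(n):
            lo = max(0, t - window)
            hi = min(n, t + window + 1)
            for j in range(lo, hi):
                if j != t:
                    C[sent[t], sent[j]] += 1.0
    return C


def ppmi_matrix(C: np.ndarray) -> np.ndarray:
    total = C.sum()
    row = C.sum(axis=1, keepdims=True)
    col = C.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(C * total / (row * col))
    pmi[~np.isfinite(pmi)] = 0.0
    return np.maximum(pmi, 0.0)


def ppmi_svd_embeddings(corpus: Corpus, window: int, dim: int) -> EmbeddingMatrix:
    """Rank-``dim`` PPMI-SVD token vectors (U * sqrt(S))."""
    P = ppmi_matrix(cooccurrence_counts(corpus, window))
    k = min(dim, P.shape[0] - 1)
    u, s, _ = svds(P, k=k, random_state=0)
    order = np.argsort(s)[::-1]
    vectors = u[:, order] * np.sqrt(s[order])
    return EmbeddingMatrix(
        list(corpus.vocabulary), vectors,
        provenance={"method": "ppmi-svd", "window": window, "dim": k},
    )
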