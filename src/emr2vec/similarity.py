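"""Concept-level similarity analysis: cosine neighbors and projection export.

The latent clinical associations that the embedding captures are read off as
cosine similarities between concept vectors: for a query concept (say a
diagnosis code) the top-k most-similar concepts, optionally restricted to
one feature category, form its neighbor report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .discretize import parse_token
from .skipgram import EmbeddingMatrix


class SimilarityError(ValueError):
    pass


def cosine_similarity(u: np.ndarray, w: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    if u.shape != w.shape:
        raise SimilarityError("vectors must share a dimension")
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        raise SimilarityError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, w) / (nu * nw))


@dataclass
class NeighborResult:
    query: str
    neighbors: list[tuple[str, float, str]]  # (token, similarity, category)

    @property
    def mean_similarity(self) -> float:
        return float(np.mean([s for _, s, _ in self.neighbors]))

    def to_json(self) -> str:
        return json.dumps(
            {
                "query": self.query,
                "neighbors": [
                    {"token": t, "similarity": s, "category": c}
                    for t, s, c in self.neighbors
                ],
            }
        )


def _category_of(token: str, category_map: Optional[Mapping[str, str]]) -> str:
    if category_map is None:
        return "other"
    if token in category_map:
        return category_map[token]
    try:
        fid, _ = parse_token(token)
    except Exception:
        return "other"
    return category_map.get(fid, "other")


def top_k_neighbors(
    query: str,
    embeddings: EmbeddingMatrix,
    k: int = 10,
    category_filter: Optional[str] = None,
    category_map: Optional[Mapping[str, str]] = None,
) -> NeighborResult:
    """The k tokens with highest cosine similarity to the query.

    The query itself is excluded; ties are broken lexicographically by
    token so rankings are reproducible. With a ``category_filter``, only
    tokens whose category (from ``category_map``) matches are ranked.
    """
    if query not in embeddings:
        raise SimilarityError(f"unknown query token: {query!r}")
    qv = embeddings.vector(query)
    qn = np.linalg.norm(qv)
    if qn == 0:
        raise SimilarityError("query has a zero vector")
    norms = np.linalg.norm(embeddings.vectors, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    sims = embeddings.vectors @ qv / (safe * qn)
    sims[norms == 0] = -np.inf
    candidates = []
    for i, tok in enumerate(embeddings.vocabulary):
        if tok == query:
            continue
        cat = _category_of(tok, category_map)
        if category_filter is not None and cat != category_filter:
            continue
        candidates.append((tok, float(sims[i]), cat))
    candidates.sort(key=lambda x: (-x[1], x[0]))
    return NeighborResult(query, candidates[:k])


def neighbors_by_category(
    query: str,
    embeddings: EmbeddingMatrix,
    category_map: Mapping[str, str],
    k: int = 10,
) -> dict[str, NeighborResult]:
    """Per-category top-k neighbor reports for one query concept."""
    cats = sorted(set(category_map.values()))
    return {
        c: top_k_neighbors(query, embeddings, k, category_filter=c,
                           category_map=category_map)
        for c in cats
    }


def neighbor_block_precision(
    embeddings: EmbeddingMatrix,
    block_map: Mapping[str, int],
    k: int = 10,
) -> float:
    """Fraction of top-k neighbors sharing the query's planted block.

    Scores every token with a nonnegative block label in ``block_map``
    (background tokens, labeled -1, are skipped as queries but count as
    wrong neighbors). The ceiling is (tokens_per_block - 1) / k when blocks
    are smaller than k + 1.
    """
    hits = total = 0
    for tok, block in sorted(block_map.items()):
        if block < 0 or tok not in embeddings:
            continue
        res = top_k_neighbors(tok, embeddings, k=k)
        hits += sum(1 for t, _, _ in res.neighbors if block_map.get(t, -2) == block)
        total += k
    if total == 0:
        raise SimilarityError("no block-labeled tokens found in the embedding")
    return hits / total


def save_neighbors_tsv(results: Sequence[NeighborResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query\trank\ttoken\tsimilarity\tcategory\n")
        for res in results:
            for rank, (tok, sim, cat) in enumerate(res.neighbors, 1):
                fh.write(f"{res.query}\t{rank}\t{tok}\t{sim:.6f}\t{cat}\n")


def export_projection_input(
    embeddings: EmbeddingMatrix,
    token_counts: Mapping[str, int],
    path: str | Path,
    min_count: int = 10,
    category_map: Optional[Mapping[str, str]] = None,
) -> int:
    """Write a TSV of (token, category, v1..vd) for a 2-D projection backend.

    Only tokens occurring at least ``min_count`` times are exported; the
    projection itself (e.g. t-SNE at perplexity 30, learning rate 200,
    1000 iterations) is delegated to external tooling. Returns the number
    of tokens written; raises if the filter empties the set.
    """
    keep = [
        t for t in embeddings.vocabulary if token_counts.get(t, 0) >= min_count
    ]
    if not keep:
        raise SimilarityError("projection subset is empty after min-count filter")
    with open(path, "w") as fh:
        header = "token\tcategory\t" + "\t".join(
            f"v{i+1}" for i in range(embeddings.dim)
        )
        fh.write(header + "\n")
        for tok in keep:
            cat = _category_of(tok, category_map)
            row = "\t".join(f"{x:.6g}" for x in embeddings.vector(tok))
            fh.write(f"{tok}\t{cat}\t{row}\n")
    return len(keep)
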