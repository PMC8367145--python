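"""Training corpus: sentences of concept tokens, vocabulary, shuffled copies.

The vocabulary is ordered lexicographically by token so that one-hot
dimensions, embedding rows and exported matrices are stable across runs and
platforms. Shuffling permutes tokens *within* each sentence (sentence order
is preserved), with one per-sentence RNG stream spawned from a master seed
so corpora are reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class CorpusError(ValueError):
    pass


@dataclass
class Corpus:
    sentences: list[list[str]]
    vocabulary: list[str] = field(default_factory=list)
    token_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.vocabulary:
            counts = Counter(tok for sent in self.sentences for tok in sent)
            self.token_counts = dict(counts)
            self.vocabulary = sorted(counts)
        self.index = {tok: i for i, tok in enumerate(self.vocabulary)}

    def __len__(self) -> int:
        return len(self.sentences)

    @property
    def vocab_size(self) -> int:
        return len(self.vocabulary)

    @property
    def max_sentence_length(self) -> int:
        return max(len(s) for s in self.sentences)

    def encoded(self) -> list[np.ndarray]:
        """Sentences as int32 arrays of vocabulary indices."""
        idx = self.index
        return [np.array([idx[t] for t in s], dtype=np.int32) for s in self.sentences]


def build_corpus(sentences: Sequence[Sequence[str]]) -> Corpus:
    """Assemble sentences into a corpus with a complete, deduplicated vocabulary."""
    sents = [list(s) for s in sentences if len(s) > 0]
    if not sents:
        raise CorpusError("corpus requires at least one nonempty sentence")
    return Corpus(sents)


def shuffle_corpus(corpus: Corpus, seed: int) -> Corpus:
    """Return a copy with each sentence's tokens independently permuted.

    Deterministic given `seed`: the master seed spawns one child stream per
    sentence, so sentence i's permutation does not depend on other sentences.
    """
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(corpus.sentences))
    shuffled = []
    for sent, child in zip(corpus.sentences, children):
        rng = np.random.default_rng(child)
        perm = rng.permutation(len(sent))
        shuffled.append([sent[j] for j in perm])
    return Corpus(shuffled, list(corpus.vocabulary), dict(corpus.token_counts))


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    """One whitespace-delimited sentence per line; loadable by any trainer."""
    with open(path, "w") as fh:
        for sent in corpus.sentences:
            fh.write(" ".join(sent) + "\n")


def load_corpus(path: str | Path) -> Corpus:
    with open(path) as fh:
        sentences = [line.split() for line in fh if line.strip()]
    return build_corpus(sentences)


def save_vocabulary(corpus: Corpus, path: str | Path) -> None:
    """TSV: token, occurrence count, vocabulary index."""
    with open(path, "w") as fh:
        fh.write("token\tcount\tindex\n")
        for i, tok in enumerate(corpus.vocabulary):
            fh.write(f"{tok}\t{corpus.token_counts[tok]}\t{i}\n")


def corpus_from_records(records, schema, edges=None) -> tuple[Corpus, dict]:
    """Convenience: tokenize a cohort and build its corpus in one step."""
    from .discretize import tokenize_cohort

    sentences, edges = tokenize_cohort(records, schema, edges)
    return build_corpus(sentences), edges
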