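"""Baseline patient representations: one-hot, multi-hot, and the mixture scheme.

The mixture representation keeps a binary multi-hot block for discrete
features and a continuous block of raw laboratory values, restricted to the
lab panel observed in at least ``coverage_threshold`` of the cohort (default
90%). Missing panel values are imputed with the cohort median. The
continuous block is z-scored by default before cosine distance so that no
single assay's scale dominates; set ``standardize=False`` to keep raw values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, CorpusError
from .records import PatientRecord
from .schema import Schema, ValueKind


def one_hot(token: str, corpus: Corpus) -> np.ndarray:
    """Binary indicator for one token at its vocabulary index."""
    if token not in corpus.index:
        raise CorpusError(f"unknown token: {token!r}")
    v = np.zeros(corpus.vocab_size, dtype=np.int8)
    v[corpus.index[token]] = 1
    return v


def multi_hot(sentence: Sequence[str], corpus: Corpus) -> np.ndarray:
    """Bitwise OR of the one-hots of every token in the sentence."""
    v = np.zeros(corpus.vocab_size, dtype=np.int8)
    for tok in sentence:
        if tok not in corpus.index:
            raise CorpusError(f"unknown token: {tok!r}")
        v[corpus.index[tok]] = 1
    return v


def multi_hot_matrix(sentences: Sequence[Sequence[str]], corpus: Corpus) -> np.ndarray:
    """n_records x vocab_size binary matrix."""
    M = np.zeros((len(sentences), corpus.vocab_size), dtype=np.int8)
    idx = corpus.index
    for i, sent in enumerate(sentences):
        for tok in sent:
            if tok not in idx:
                raise CorpusError(f"unknown token: {tok!r}")
            M[i, idx[tok]] = 1
    return M


@dataclass
class LabPanel:
    """The retained lab panel: feature ids, cohort medians, optional z-scaling."""

    feature_ids: list[str]
    medians: np.ndarray
    means: np.ndarray
    stds: np.ndarray
    coverage_threshold: float
    standardize: bool = True


def fit_lab_panel(
    records: Sequence[PatientRecord],
    schema: Schema,
    coverage_threshold: float = 0.90,
    standardize: bool = True,
) -> LabPanel:
    """Select labs observed in >= coverage_threshold of records; fit medians.

    Raises if no lab clears the threshold (an empty continuous block would
    make the mixture scheme meaningless).
    """
    lab_ids = [
        f.feature_id for f in schema if f.value_kind is ValueKind.LAB_REFERENCE
    ]
    n = len(records)
    cols = {}
    for fid in lab_ids:
        vals = np.array(
            [float(r.values[fid]) for r in records if fid in r.values], dtype=float
        )
        if n > 0 and vals.size / n >= coverage_threshold:
            cols[fid] = vals
    if not cols:
        raise CorpusError(
            f"no lab observed in >= {coverage_threshold:.0%} of the cohort"
        )
    ids = sorted(cols)
    medians = np.array([np.median(cols[f]) for f in ids])
    means = np.array([cols[f].mean() for f in ids])
    stds = np.array([cols[f].std() for f in ids])
    stds[stds == 0] = 1.0
    return LabPanel(ids, medians, means, stds, coverage_threshold, standardize)


@dataclass
class MixtureVector:
    discrete_bits: np.ndarray
    continuous_values: np.ndarray


def mixture_vector(
    record: PatientRecord,
    sentence: Sequence[str],
    corpus: Corpus,
    panel: LabPanel,
) -> MixtureVector:
    """Mixture representation of one record.

    Discrete block: multi-hot over the record's non-panel tokens. Continuous
    block: the record's raw values for each panel lab, median-imputed when
    missing, z-scored if the panel says so.
    """
    panel_set = set(panel.feature_ids)
    discrete_tokens = [t for t in sentence if t.partition("=")[0] not in panel_set]
    bits = multi_hot(discrete_tokens, corpus)
    cont = panel.medians.copy()
    for j, fid in enumerate(panel.feature_ids):
        if fid in record.values:
            cont[j] = float(record.values[fid])
    if panel.standardize:
        cont = (cont - panel.means) / panel.stds
    return MixtureVector(bits, cont)


def mixture_matrix(
    records: Sequence[PatientRecord],
    sentences: Sequence[Sequence[str]],
    corpus: Corpus,
    panel: LabPanel,
) -> tuple[np.ndarray, np.ndarray]:
    """(discrete n x V binary, continuous n x p real) blocks for a cohort."""
    vecs = [
        mixture_vector(r, s, corpus, panel) for r, s in zip(records, sentences)
    ]
    return (
        np.stack([v.discrete_bits for v in vecs]),
        np.stack([v.continuous_values for v in vecs]),
    )


def save_matrix_csv(M: np.ndarray, ids: Sequence[str], path: str | Path) -> None:
    pd.DataFrame(M, index=list(ids)).to_csv(path, index_label="patient_id")


def save_sparse_coo(M: np.ndarray, path: str | Path) -> None:
    """Plain-text coordinate format: ``row col value`` per nonzero."""
    rows, cols = np.nonzero(M)
    with open(path, "w") as fh:
        fh.write(f"%n_rows {M.shape[0]} n_cols {M.shape[1]} nnz {rows.size}\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r} {c} {M[r, c]}\n")
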