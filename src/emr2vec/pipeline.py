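"""End-to-end orchestration: tokenize -> corpus -> represent -> cluster -> evaluate.

A :class:`RunConfig` names one representation scheme. The embedding schemes
differ in corpus treatment (shuffle ensemble, initial order, or
maximum-window initial order); the reference schemes are the multi-hot and
mixture encodings. Optionally the corpus used for training can be the full
cohort while clustering is evaluated on a labeled subcohort, which is how
full-corpus and subcohort-corpus variants of each embedding scheme are
expressed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import cluster, select_k
from .corpus import Corpus, build_corpus
from .discretize import fit_cohort_edges, record_to_sentence
from .distances import DistanceSpec, pairwise
from .records import PatientRecord
from .representations import fit_lab_panel, mixture_matrix, multi_hot_matrix
from .schema import Schema
from .skipgram import EmbeddingMatrix, TrainConfig, embed_patients, ensemble_embed, train_skipgram
from .validity import ValidityReport, davies_bouldin_index, hopkins_statistic, map_and_score, silhouette_index

SCHEMES = (
    "embedding-shuffled",
    "embedding-unshuffled",
    "embedding-maxwindow",
    "multi-hot",
    "mixture",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    scheme: str = "embedding-shuffled"
    train: TrainConfig = field(default_factory=TrainConfig)
    k_range: tuple[int, int] = (2, 15)
    coverage_threshold: float = 0.90
    standardize_mixture: bool = True
    n_init: int = 10
    seed: int = 0
    hopkins_m: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise PipelineError(f"unknown scheme {self.scheme!r}; one of {SCHEMES}")


@dataclass
class PipelineResult:
    scheme: str
    representation: np.ndarray      # patients x dims (or concatenated mixture)
    distance: DistanceSpec
    k_star: int
    si_by_k: dict[int, float]
    solution: object
    report: ValidityReport
    embeddings: Optional[EmbeddingMatrix] = None
    manifest: dict = field(default_factory=dict)


def represent_patients(
    config: RunConfig,
    records: Sequence[PatientRecord],
    schema: Schema,
    train_records: Optional[Sequence[PatientRecord]] = None,
) -> tuple[np.ndarray, DistanceSpec, Optional[EmbeddingMatrix]]:
    """Build the patient matrix and its distance for the configured scheme."""
    train_records = list(train_records) if train_records is not None else list(records)
    edges = fit_cohort_edges(train_records, schema)
    train_sentences = [record_to_sentence(r, schema, edges) for r in train_records]
    eval_sentences = [record_to_sentence(r, schema, edges) for r in records]
    corpus = build_corpus(train_sentences)
    scheme = config.scheme
    if scheme == "multi-hot":
        X = multi_hot_matrix(eval_sentences, corpus).astype(np.float64)
        return X, DistanceSpec("jaccard"), None
    if scheme == "mixture":
        panel = fit_lab_panel(train_records, schema, config.coverage_threshold,
                              standardize=config.standardize_mixture)
        disc, cont = mixture_matrix(records, eval_sentences, corpus, panel)
        X = np.hstack([disc.astype(np.float64), cont])
        return X, DistanceSpec("mixed", split=disc.shape[1]), None
    tc = config.train
    if scheme == "embedding-shuffled":
        emb = ensemble_embed(corpus, tc)
    elif scheme == "embedding-unshuffled":
        emb = train_skipgram(corpus, tc)
    else:  # embedding-maxwindow: initial order, window = longest sentence
        from dataclasses import replace
        emb = train_skipgram(corpus, replace(tc, window="max"))
    X = embed_patients(eval_sentences, emb)
    return X, DistanceSpec("cosine"), emb


def run_pipeline(
    config: RunConfig,
    records: Sequence[PatientRecord],
    schema: Schema,
    true_labels: Optional[dict[str, str]] = None,
    train_records: Optional[Sequence[PatientRecord]] = None,
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run one scheme end to end; idempotent given the seeds in config."""
    X, dist, emb = represent_patients(config, records, schema, train_records)
    D = pairwise(dist, X)
    hopkins = hopkins_statistic(X, dist, m=config.hopkins_m, seed=config.seed)
    lo, hi = config.k_range
    k_star, si_by_k, solutions = select_k(
        X, dist, range(lo, hi + 1), seed=config.seed, n_init=config.n_init, D=D
    )
    sol = solutions[k_star]
    report = ValidityReport(
        hopkins=hopkins,
        silhouette=si_by_k[k_star],
        dbi=davies_bouldin_index(X, sol, dist, D=D),
    )
    if true_labels is not None:
        labels = [true_labels[r.patient_id] for r in records]
        scored = map_and_score(sol.assignments, labels)
        report.per_class = scored.per_class
        report.cluster_label_map = scored.cluster_label_map
    manifest = {
        "scheme": config.scheme,
        "seed": config.seed,
        "k_star": k_star,
        "n_patients": len(records),
        "config_hash": hashlib.sha256(
            json.dumps(
                {"scheme": config.scheme, "seed": config.seed,
                 "k_range": list(config.k_range), "dim": config.train.dim,
                 "window": config.train.window, "epochs": config.train.epochs,
                 "n_shuffles": config.train.n_shuffles},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
    }
    result = PipelineResult(config.scheme, X, dist, k_star, si_by_k, sol,
                            report, emb, manifest)
    if outdir is not None:
        _write_artifacts(result, records, outdir)
    return result


def _write_artifacts(res: PipelineResult, records, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "cluster": res.solution.assignments,
    }).to_csv(out / "assignments.csv", index=False)
    res.report.to_json(out / "validity.json")
    (out / "manifest.json").write_text(json.dumps(res.manifest, indent=1))
    pd.DataFrame(
        {"k": list(res.si_by_k), "silhouette": list(res.si_by_k.values())}
    ).to_csv(out / "silhouette_by_k.csv", index=False)
    if res.embeddings is not None:
        res.embeddings.save_text(out / "embeddings.txt")


def compare_schemes(
    records: Sequence[PatientRecord],
    schema: Schema,
    true_labels: Optional[dict[str, str]] = None,
    schemes: Sequence[str] = SCHEMES,
    base_config: Optional[RunConfig] = None,
    train_records: Optional[Sequence[PatientRecord]] = None,
) -> pd.DataFrame:
    """Run several schemes on one cohort; one row per scheme (Hopkins, SI, DBI, F1)."""
    from dataclasses import replace as dc_replace

    base = base_config or RunConfig()
    rows = []
    for scheme in schemes:
        cfg = dc_replace(base, scheme=scheme)
        res = run_pipeline(cfg, records, schema, true_labels, train_records)
        row = {
            "scheme": scheme,
            "k_star": res.k_star,
            "hopkins": res.report.hopkins,
            "silhouette": res.report.silhouette,
            "dbi": res.report.dbi,
        }
        for lab, scores in res.report.per_class.items():
            row[f"f1_{lab}"] = scores["f1"]
        rows.append(row)
    return pd.DataFrame(rows)
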