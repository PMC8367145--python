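"""Discretization of raw feature values into medical-concept tokens.

Every raw value maps to exactly one discrete *medical concept* — a
``feature_id=value`` token. Continuous features are binned: age into five
fixed clinical bins, laboratory values by their reference range (2- or
3-class), and other continuous features into cohort quartiles. A patient
record then reads as a *sentence* of concept tokens, one per present
non-outcome feature; missing features simply contribute no token.

Boundary conventions (recorded because reasonable alternatives exist):

* age boundaries 18/35/45/60 belong to the upper bin, matching the bin
  labels ``<18, 18-34, 35-44, 45-59, >=60``;
* the lab reference interval is closed, ``lo <= v <= hi`` is medium/normal;
* quartile edges are right-closed: a value equal to an edge falls in the
  lower bin; values outside the fitted range clamp to the outer bins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import PatientRecord
from .schema import Category, FeatureSpec, Schema, ValueKind


class DiscretizationError(ValueError):
    pass


@dataclass(frozen=True)
class MedicalConcept:
    """A (feature, discrete value) pair; the 'word' of the concept corpus."""

    feature_id: str
    value: str
    category: Category

    @property
    def token(self) -> str:
        return f"{self.feature_id}={self.value}"


ConceptSentence = list[str]

AGE_LABELS = ("lt18", "18-34", "35-44", "45-59", "ge60")
_AGE_EDGES = (18.0, 35.0, 45.0, 60.0)


def format_token(feature_id: str, value: str) -> str:
    return f"{feature_id}={value}"


def parse_token(token: str) -> tuple[str, str]:
    """Inverse of :func:`format_token`; splits at the first ``=``."""
    fid, sep, value = token.partition("=")
    if not sep or not fid or not value:
        raise DiscretizationError(f"malformed concept token: {token!r}")
    return fid, value


def bin_age(age: float, feature_id: str = "age") -> MedicalConcept:
    """Assign an age in years to one of the five clinical age bins."""
    if not math.isfinite(age) or age < 0:
        raise DiscretizationError(f"invalid age: {age}")
    idx = int(np.searchsorted(_AGE_EDGES, age, side="right"))
    return MedicalConcept(feature_id, AGE_LABELS[idx], Category.DEMOGRAPHICS)


def bin_lab(value: float, spec: FeatureSpec) -> MedicalConcept:
    """Classify a lab value against its reference range.

    3-class: low / medium / high; 2-class: normal / abnormal. The reference
    interval is closed on both ends.
    """
    if spec.value_kind is not ValueKind.LAB_REFERENCE:
        raise DiscretizationError(f"{spec.feature_id} is not a lab_reference feature")
    if not isinstance(value, (int, float)) or not math.isfinite(value):
        raise DiscretizationError(f"{spec.feature_id}: non-finite lab value {value!r}")
    lo, hi = spec.reference_range  # type: ignore[misc]
    if spec.n_lab_classes == 3:
        label = "low" if value < lo else ("high" if value > hi else "medium")
    else:
        label = "normal" if lo <= value <= hi else "abnormal"
    return MedicalConcept(spec.feature_id, label, spec.category)


@dataclass(frozen=True)
class BinEdges:
    """Frozen 25/50/75-percentile edges for one quartile-binned feature."""

    feature_id: str
    edges: tuple[float, float, float]

    def assign(self, value: float) -> int:
        """Quartile index 0..3; right-closed bins, out-of-range clamps."""
        if not math.isfinite(value):
            raise DiscretizationError(f"{self.feature_id}: non-finite value {value!r}")
        q1, q2, q3 = self.edges
        if value <= q1:
            return 0
        if value <= q2:
            return 1
        if value <= q3:
            return 2
        return 3


QUARTILE_LABELS = ("q1", "q2", "q3", "q4")


def fit_quartile_bins(values: Sequence[float], feature_id: str = "feature") -> BinEdges:
    """Fit quartile edges (25/50/75 percentiles) on a cohort's observed values."""
    arr = np.asarray([v for v in values if v is not None and math.isfinite(v)], dtype=float)
    if np.unique(arr).size < 4:
        raise DiscretizationError(
            f"degenerate feature {feature_id!r}: need >= 4 distinct values for quartiles"
        )
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return BinEdges(feature_id, (float(q1), float(q2), float(q3)))


def apply_quartile_bin(value: float, edges: BinEdges, category: Category) -> MedicalConcept:
    return MedicalConcept(edges.feature_id, QUARTILE_LABELS[edges.assign(value)], category)


def save_edges(edges_map: dict[str, BinEdges], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({fid: list(e.edges) for fid, e in edges_map.items()}, fh, indent=1)


def load_edges(path: str | Path) -> dict[str, BinEdges]:
    with open(path) as fh:
        raw = json.load(fh)
    return {fid: BinEdges(fid, tuple(e)) for fid, e in raw.items()}


def fit_cohort_edges(records: Sequence[PatientRecord], schema: Schema) -> dict[str, BinEdges]:
    """Fit quartile edges for every continuous_quartile feature over a cohort."""
    edges: dict[str, BinEdges] = {}
    for spec in schema.quartile_features:
        vals = [
            float(rec.values[spec.feature_id])
            for rec in records
            if spec.feature_id in rec.values
        ]
        if not vals:  # feature absent from this cohort: nothing to fit
            continue
        edges[spec.feature_id] = fit_quartile_bins(vals, spec.feature_id)
    return edges


def _concept_for(spec: FeatureSpec, raw, edges: dict[str, BinEdges]) -> MedicalConcept:
    if spec.value_kind is ValueKind.AGE:
        return bin_age(float(raw), spec.feature_id)
    if spec.value_kind is ValueKind.LAB_REFERENCE:
        return bin_lab(float(raw), spec)
    if spec.value_kind is ValueKind.CONTINUOUS_QUARTILE:
        if spec.feature_id not in edges:
            raise DiscretizationError(f"no fitted edges for {spec.feature_id!r}")
        return apply_quartile_bin(float(raw), edges[spec.feature_id], spec.category)
    value = str(raw)
    if any(ch.isspace() for ch in value):
        value = value.replace(" ", "_")
    return MedicalConcept(spec.feature_id, value, spec.category)


def record_to_sentence(
    record: PatientRecord,
    schema: Schema,
    edges: dict[str, BinEdges] | None = None,
) -> ConceptSentence:
    """Tokenize one record into its concept sentence.

    One token per present non-outcome feature, in schema order (the initial,
    pre-shuffle order). Missing features are skipped — the corpus path never
    imputes. Raises if the schema does not cover a present feature or if no
    non-outcome feature remains.
    """
    edges = edges or {}
    for fid in record.values:
        if fid not in schema:
            raise DiscretizationError(
                f"{record.patient_id}: feature {fid!r} not in schema"
            )
    sentence: ConceptSentence = []
    for spec in schema.corpus_features:
        if spec.feature_id not in record.values:
            continue
        raw = record.values[spec.feature_id]
        sentence.append(_concept_for(spec, raw, edges).token)
    if not sentence:
        raise DiscretizationError(
            f"{record.patient_id}: record contains no non-outcome features"
        )
    return sentence


def tokenize_cohort(
    records: Sequence[PatientRecord],
    schema: Schema,
    edges: dict[str, BinEdges] | None = None,
) -> tuple[list[ConceptSentence], dict[str, BinEdges]]:
    """Fit quartile edges (if not given) and tokenize every record."""
    if edges is None:
        edges = fit_cohort_edges(records, schema)
    return [record_to_sentence(r, schema, edges) for r in records], edges
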