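"""Feature schema: categories, value kinds, and per-feature discretization rules.

A schema is a list of :class:`FeatureSpec`, one per raw feature. It declares
how each feature is turned into a medical-concept token (categorical
pass-through, age bins, quartile bins, or lab reference-range classes) and
which features are outcomes and therefore never enter the training corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml


class Category(str, Enum):
    """The seven feature categories of a structured EMR, plus outcomes."""

    DEMOGRAPHICS = "demographics"
    ADMISSION = "admission"
    RESOURCES = "resources"
    DIAGNOSIS = "diagnosis"
    PROCEDURE = "procedure"
    LAB = "lab"
    MEDICATION = "medication"
    OUTCOME = "outcome"


class ValueKind(str, Enum):
    CATEGORICAL = "categorical"
    CONTINUOUS_QUARTILE = "continuous_quartile"
    LAB_REFERENCE = "lab_reference"
    AGE = "age"


class SchemaError(ValueError):
    """Raised when a feature spec or schema violates its invariants."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one raw feature and its discretization rule.

    Parameters
    ----------
    feature_id:
        Unique feature name; becomes the left-hand side of tokens
        ``feature_id=value``.
    category:
        One of the seven EMR categories or ``outcome``.
    value_kind:
        How raw values are discretized.
    reference_range:
        ``(lo, hi)`` clinical reference interval; required (and only legal)
        for ``lab_reference`` features.
    n_lab_classes:
        2 (normal/abnormal) or 3 (low/medium/high); required iff
        ``value_kind == lab_reference``.
    """

    feature_id: str
    category: Category
    value_kind: ValueKind = ValueKind.CATEGORICAL
    reference_range: Optional[tuple[float, float]] = None
    n_lab_classes: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "value_kind", ValueKind(self.value_kind))
        if self.value_kind is ValueKind.LAB_REFERENCE:
            if self.reference_range is None:
                raise SchemaError(
                    f"{self.feature_id}: lab_reference requires a reference_range"
                )
            lo, hi = self.reference_range
            if not (lo < hi):
                raise SchemaError(f"{self.feature_id}: reference range must have lo < hi")
            object.__setattr__(self, "reference_range", (float(lo), float(hi)))
            if self.n_lab_classes not in (2, 3):
                raise SchemaError(
                    f"{self.feature_id}: n_lab_classes must be 2 or 3 for lab features"
                )
        else:
            if self.n_lab_classes is not None:
                raise SchemaError(
                    f"{self.feature_id}: n_lab_classes only valid for lab_reference"
                )
        if "=" in self.feature_id or any(ch.isspace() for ch in self.feature_id):
            raise SchemaError(
                f"feature_id {self.feature_id!r} may not contain '=' or whitespace"
            )

    @property
    def is_outcome(self) -> bool:
        return self.category is Category.OUTCOME


@dataclass
class Schema:
    """An ordered collection of feature specs; order fixes initial token order."""

    features: list[FeatureSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate feature ids: {dupes}")
        self._by_id = {f.feature_id: f for f in self.features}

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, feature_id: str) -> FeatureSpec:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    @property
    def corpus_features(self) -> list[FeatureSpec]:
        """Features that may contribute tokens (everything but outcomes)."""
        return [f for f in self.features if not f.is_outcome]

    @property
    def quartile_features(self) -> list[FeatureSpec]:
        return [f for f in self.features if f.value_kind is ValueKind.CONTINUOUS_QUARTILE]

    def to_dict(self) -> dict:
        out = {}
        for f in self.features:
            entry: dict = {
                "category": f.category.value,
                "value_kind": f.value_kind.value,
            }
            if f.reference_range is not None:
                entry["reference_range"] = list(f.reference_range)
            if f.n_lab_classes is not None:
                entry["n_lab_classes"] = f.n_lab_classes
            out[f.feature_id] = entry
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Schema":
        feats = []
        for fid, entry in d.items():
            rr = entry.get("reference_range")
            feats.append(
                FeatureSpec(
                    feature_id=fid,
                    category=Category(entry["category"]),
                    value_kind=ValueKind(entry.get("value_kind", "categorical")),
                    reference_range=tuple(rr) if rr is not None else None,
                    n_lab_classes=entry.get("n_lab_classes"),
                )
            )
        return cls(feats)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "Schema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
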