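"""Patient record data model and JSON-Lines / CSV input-output.

One record per patient: the first admission only. ``values`` holds raw
feature values keyed by feature id (strings for categorical features, reals
for continuous ones); ``outcome`` holds the held-out outcome fields, which
never enter the training corpus.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

import pandas as pd

RawValue = Union[str, float, int, bool]

OUTCOME_FIELDS = ("length_of_stay", "cost", "discharge_route", "death")


class RecordError(ValueError):
    """Raised for records violating the data-model invariants."""


@dataclass
class PatientRecord:
    patient_id: str
    values: dict[str, RawValue] = field(default_factory=dict)
    outcome: dict[str, RawValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise RecordError("patient_id must be nonempty")
        if not self.values:
            raise RecordError(
                f"{self.patient_id}: record has no non-outcome features"
            )

    def to_json(self) -> str:
        return json.dumps(
            {"patient_id": self.patient_id, "values": self.values, "outcome": self.outcome},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "PatientRecord":
        d = json.loads(line)
        return cls(d["patient_id"], d.get("values", {}), d.get("outcome", {}))


def write_jsonl(records: Iterable[PatientRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_jsonl(path: str | Path) -> list[PatientRecord]:
    records = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = PatientRecord.from_json(line)
            if rec.patient_id in seen:
                raise RecordError(f"duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)
            records.append(rec)
    return records


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Wide table: one row per patient, outcome columns prefixed ``outcome.``."""
    rows = []
    for rec in records:
        row: dict = {"patient_id": rec.patient_id}
        row.update(rec.values)
        row.update({f"outcome.{k}": v for k, v in rec.outcome.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    if "patient_id" not in df.columns:
        raise RecordError("CSV must have a patient_id column")
    out_cols = [c for c in df.columns if c.startswith("outcome.")]
    val_cols = [c for c in df.columns if c != "patient_id" and c not in out_cols]
    records = []
    for _, row in df.iterrows():
        values = {c: row[c] for c in val_cols if not _is_missing(row[c])}
        outcome = {c[len("outcome."):]: row[c] for c in out_cols if not _is_missing(row[c])}
        records.append(PatientRecord(str(row["patient_id"]), values, outcome))
    return records


def write_csv(records: Iterable[PatientRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_csv(path: str | Path) -> list[PatientRecord]:
    return frame_to_records(pd.read_csv(path))


def iter_records(path: str | Path) -> Iterator[PatientRecord]:
    """Load records from .jsonl/.ndjson or .csv by extension."""
    p = Path(path)
    if p.suffix in (".jsonl", ".ndjson", ".json"):
        yield from read_jsonl(p)
    elif p.suffix == ".csv":
        yield from read_csv(p)
    else:
        raise RecordError(f"unrecognized record file extension: {p.suffix}")
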