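"""Synthetic structured-EMR cohorts with planted latent disease classes.

The generator emulates a single-admission stroke-like cohort: two latent
classes (ischemic-like vs hemorrhagic-like, default 83/17 mix), class-
conditional prevalences for diagnosis/procedure/medication concepts,
class-conditional Gaussian laboratory values with reference ranges and
missing-at-random gaps, quartile-binnable resource-utilization features, and
class-dependent outcome fields (length of stay, cost, death, discharge
route) that are kept out of the training corpus.

Everything is deterministic given the master seed, which spawns one named
substream per component (class draw, demographics, concepts, labs,
missingness, outcomes), so individual components are reproducible in
isolation. The generator also returns a concept ledger — every token it can
emit, with its true class association — which is the ground truth that
similarity and clustering evaluations are scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .corpus import Corpus, build_corpus
from .records import PatientRecord
from .schema import Category, FeatureSpec, Schema, ValueKind


class SpecError(ValueError):
    pass


@dataclass
class ClassSpec:
    name: str
    proportion: float
    age_mean: float
    age_sd: float
    los_logmean: float      # log-days
    los_logsd: float
    cost_logmean: float     # log-(thousand currency units)
    cost_logsd: float
    death_rate: float
    discharge_probs: dict[str, float]  # route -> probability


@dataclass
class CategoricalFeature:
    feature_id: str
    category: Category
    levels: list[str]
    class_probs: dict[str, list[float]]  # class name -> probs over levels


@dataclass
class QuartileFeature:
    feature_id: str
    category: Category
    class_mean: dict[str, float]
    class_sd: dict[str, float]


@dataclass
class BinaryConcept:
    """A presence/absence concept (diagnosis, procedure or medication code)."""

    feature_id: str
    category: Category
    class_prevalence: dict[str, float]


@dataclass
class LabItem:
    feature_id: str
    reference_range: tuple[float, float]
    n_classes: int                     # 2 or 3 reference classes
    missingness: float
    class_mean: dict[str, float]
    class_sd: dict[str, float]


@dataclass
class CohortSpec:
    n_patients: int
    classes: list[ClassSpec]
    categoricals: list[CategoricalFeature] = field(default_factory=list)
    quartiles: list[QuartileFeature] = field(default_factory=list)
    binaries: list[BinaryConcept] = field(default_factory=list)
    labs: list[LabItem] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise SpecError("n_patients must be >= 1")
        props = [c.proportion for c in self.classes]
        if abs(sum(props) - 1.0) > 1e-9 or any(p <= 0 for p in props):
            raise SpecError("class mixing proportions must be positive and sum to 1")
        for b in self.binaries:
            if any(not (0 <= p <= 1) for p in b.class_prevalence.values()):
                raise SpecError(f"{b.feature_id}: prevalence outside [0,1]")
        for lab in self.labs:
            if not (0 <= lab.missingness < 1):
                raise SpecError(f"{lab.feature_id}: missingness outside [0,1)")
            lo, hi = lab.reference_range
            if not lo < hi:
                raise SpecError(f"{lab.feature_id}: bad reference range")

    @property
    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]


def default_cohort_spec(n_patients: int = 8000, seed: int = 0) -> CohortSpec:
    """The default two-class stroke-like cohort.

    Sized to mirror a realistic inpatient stroke cohort in shape: ~83/17
    ischemic-like vs hemorrhagic-like mix, ~400 diagnosis codes of which a
    minority are class markers, ~30 procedures, ~40 medications, 60 lab
    items at roughly 90% coverage, and class-separated outcomes.
    """
    is_, hs = "IS", "HS"
    classes = [
        ClassSpec(is_, 0.83, age_mean=70, age_sd=11,
                  los_logmean=2.2, los_logsd=0.4,
                  cost_logmean=2.8, cost_logsd=0.6, death_rate=0.0065,
                  discharge_probs={"home": 0.85, "transfer": 0.14, "against_advice": 0.01}),
        ClassSpec(hs, 0.17, age_mean=58, age_sd=13,
                  los_logmean=2.5, los_logsd=0.5,
                  cost_logmean=4.7, cost_logsd=0.5, death_rate=0.07,
                  discharge_probs={"home": 0.60, "transfer": 0.38, "against_advice": 0.02}),
    ]
    categoricals = [
        CategoricalFeature("sex", Category.DEMOGRAPHICS, ["male", "female"],
                           {is_: [0.55, 0.45], hs: [0.62, 0.38]}),
        CategoricalFeature("admission_type", Category.ADMISSION,
                           ["emergency", "elective"],
                           {is_: [0.75, 0.25], hs: [0.92, 0.08]}),
        CategoricalFeature("admission_ward", Category.ADMISSION,
                           ["neurology", "neurosurgery", "icu"],
                           {is_: [0.80, 0.10, 0.10], hs: [0.30, 0.45, 0.25]}),
    ]
    quartiles = [
        QuartileFeature("icu_hours", Category.RESOURCES,
                        {is_: 6.0, hs: 48.0}, {is_: 8.0, hs: 30.0}),
        QuartileFeature("n_imaging_studies", Category.RESOURCES,
                        {is_: 3.0, hs: 6.0}, {is_: 1.5, hs: 2.5}),
    ]
    binaries: list[BinaryConcept] = []
    # diagnosis codes: 40 ischemic markers, 40 hemorrhagic markers, 320 background
    for j in range(40):
        binaries.append(BinaryConcept(f"dxI{j:03d}", Category.DIAGNOSIS,
                                      {is_: 0.15, hs: 0.02}))
        binaries.append(BinaryConcept(f"dxH{j:03d}", Category.DIAGNOSIS,
                                      {is_: 0.02, hs: 0.15}))
    for j in range(320):
        p = 0.005 + 0.025 * (j % 10) / 9  # background comorbidities, both classes
        binaries.append(BinaryConcept(f"dxB{j:03d}", Category.DIAGNOSIS,
                                      {is_: p, hs: p}))
    for j in range(8):
        binaries.append(BinaryConcept(f"prI{j:02d}", Category.PROCEDURE,
                                      {is_: 0.30, hs: 0.05}))
        binaries.append(BinaryConcept(f"prH{j:02d}", Category.PROCEDURE,
                                      {is_: 0.03, hs: 0.35}))
    for j in range(14):
        binaries.append(BinaryConcept(f"prB{j:02d}", Category.PROCEDURE,
                                      {is_: 0.05, hs: 0.05}))
    for j in range(10):
        binaries.append(BinaryConcept(f"rxI{j:02d}", Category.MEDICATION,
                                      {is_: 0.40, hs: 0.05}))
        binaries.append(BinaryConcept(f"rxH{j:02d}", Category.MEDICATION,
                                      {is_: 0.05, hs: 0.35}))
    for j in range(20):
        binaries.append(BinaryConcept(f"rxB{j:02d}", Category.MEDICATION,
                                      {is_: 0.08, hs: 0.08}))
    labs: list[LabItem] = []
    miss_cycle = (0.05, 0.08, 0.12)
    for j in range(60):
        lo = 2.0 + j
        hi = lo + 2.0 + 0.05 * j
        mid = 0.5 * (lo + hi)
        width = hi - lo
        if j < 15:  # discriminative panel: shifted in the hemorrhagic-like class
            mean = {is_: mid, hs: hi + 0.6 * width}
        else:
            mean = {is_: mid, hs: mid}
        labs.append(LabItem(
            feature_id=f"lab{j:02d}",
            reference_range=(lo, hi),
            n_classes=2 if j % 2 == 0 else 3,
            missingness=miss_cycle[j % 3],
            class_mean=mean,
            class_sd={is_: 0.45 * width, hs: 0.45 * width},
        ))
    return CohortSpec(n_patients, classes, categoricals, quartiles, binaries,
                      labs, seed=seed)


def schema_for(spec: CohortSpec) -> Schema:
    """The feature schema matching a cohort spec (including outcome fields)."""
    feats: list[FeatureSpec] = [
        FeatureSpec("age", Category.DEMOGRAPHICS, ValueKind.AGE),
    ]
    for c in spec.categoricals:
        feats.append(FeatureSpec(c.feature_id, c.category, ValueKind.CATEGORICAL))
    for q in spec.quartiles:
        feats.append(FeatureSpec(q.feature_id, q.category, ValueKind.CONTINUOUS_QUARTILE))
    for b in spec.binaries:
        feats.append(FeatureSpec(b.feature_id, b.category, ValueKind.CATEGORICAL))
    for lab in spec.labs:
        feats.append(FeatureSpec(lab.feature_id, Category.LAB, ValueKind.LAB_REFERENCE,
                                 reference_range=lab.reference_range,
                                 n_lab_classes=lab.n_classes))
    for out in ("length_of_stay", "cost", "discharge_route", "death"):
        feats.append(FeatureSpec(out, Category.OUTCOME, ValueKind.CATEGORICAL))
    return Schema(feats)


def concept_ledger(spec: CohortSpec) -> pd.DataFrame:
    """Every token the generator can emit, with category and class association.

    Association is the class in which the concept is most prevalent
    ("shared" when prevalences are equal across classes).
    """
    rows = []
    from .discretize import AGE_LABELS, QUARTILE_LABELS

    for lbl in AGE_LABELS:
        rows.append(("age=" + lbl, Category.DEMOGRAPHICS.value, "shared"))
    for c in spec.categoricals:
        for lvl in c.levels:
            rows.append((f"{c.feature_id}={lvl}", c.category.value, "shared"))
    for q in spec.quartiles:
        for lbl in QUARTILE_LABELS:
            rows.append((f"{q.feature_id}={lbl}", q.category.value, "shared"))
    for b in spec.binaries:
        prev = b.class_prevalence
        best = max(prev, key=lambda k: prev[k])
        assoc = "shared" if len(set(prev.values())) == 1 else best
        rows.append((f"{b.feature_id}=present", b.category.value, assoc))
    for lab in spec.labs:
        labels = ("normal", "abnormal") if lab.n_classes == 2 else ("low", "medium", "high")
        means = lab.class_mean
        assoc = "shared" if len(set(means.values())) == 1 else max(means, key=lambda k: means[k])
        for lbl in labels:
            lo, hi = lab.reference_range
            in_range = lbl in ("normal", "medium")
            rows.append((f"{lab.feature_id}={lbl}", Category.LAB.value,
                         "shared" if in_range else assoc))
    return pd.DataFrame(rows, columns=["token", "category", "association"])


def generate_cohort(
    spec: CohortSpec, seed: Optional[int] = None
) -> tuple[list[PatientRecord], dict[str, str], pd.DataFrame]:
    """Draw a cohort: records, patient->class ground truth, concept ledger."""
    spec.validate()
    seed = spec.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(6)
    rng_class, rng_demo, rng_concepts, rng_labs, rng_miss, rng_out = (
        np.random.default_rng(s) for s in streams
    )
    n = spec.n_patients
    props = np.array([c.proportion for c in spec.classes])
    class_idx = rng_class.choice(len(spec.classes), size=n, p=props)
    names = spec.class_names
    values: list[dict] = [dict() for _ in range(n)]

    # demographics: age per class
    for ci, cls in enumerate(spec.classes):
        mask = class_idx == ci
        ages = rng_demo.normal(cls.age_mean, cls.age_sd, size=int(mask.sum()))
        ages = np.clip(ages, 0.0, 105.0)
        for i, a in zip(np.flatnonzero(mask), ages):
            values[i]["age"] = round(float(a), 1)
    for c in spec.categoricals:
        for ci, cls in enumerate(spec.classes):
            mask = class_idx == ci
            draws = rng_demo.choice(len(c.levels), size=int(mask.sum()),
                                    p=c.class_probs[cls.name])
            for i, d in zip(np.flatnonzero(mask), draws):
                values[i][c.feature_id] = c.levels[d]
    for q in spec.quartiles:
        means = np.array([q.class_mean[nm] for nm in names])[class_idx]
        sds = np.array([q.class_sd[nm] for nm in names])[class_idx]
        vals = np.maximum(rng_demo.normal(means, sds), 0.0)
        for i in range(n):
            values[i][q.feature_id] = round(float(vals[i]), 2)

    # presence/absence concepts, class-conditional Bernoulli
    for b in spec.binaries:
        p = np.array([b.class_prevalence[nm] for nm in names])[class_idx]
        hits = rng_concepts.random(n) < p
        for i in np.flatnonzero(hits):
            values[i][b.feature_id] = "present"

    # labs: class-conditional normals, then missing-at-random mask
    for lab in spec.labs:
        means = np.array([lab.class_mean[nm] for nm in names])[class_idx]
        sds = np.array([lab.class_sd[nm] for nm in names])[class_idx]
        vals = rng_labs.normal(means, sds)
        observed = rng_miss.random(n) >= lab.missingness
        for i in np.flatnonzero(observed):
            values[i][lab.feature_id] = round(float(vals[i]), 3)

    # outcomes, excluded from the corpus downstream
    records = []
    ground_truth: dict[str, str] = {}
    for i in range(n):
        cls = spec.classes[class_idx[i]]
        routes = sorted(cls.discharge_probs)
        probs = np.array([cls.discharge_probs[r] for r in routes])
        death = bool(rng_out.random() < cls.death_rate)
        outcome = {
            "length_of_stay": round(float(rng_out.lognormal(cls.los_logmean, cls.los_logsd)), 1),
            "cost": round(float(rng_out.lognormal(cls.cost_logmean, cls.cost_logsd)), 2),
            "discharge_route": "death" if death else str(
                rng_out.choice(routes, p=probs / probs.sum())
            ),
            "death": death,
        }
        pid = f"p{i:06d}"
        records.append(PatientRecord(pid, values[i], outcome))
        ground_truth[pid] = cls.name
    return records, ground_truth, concept_ledger(spec)


def make_planted_block_corpus(
    n_blocks: int = 4,
    tokens_per_block: int = 10,
    n_sentences: int = 2000,
    seed: int = 0,
    n_noise_tokens: int = 100,
    block_tokens_per_sentence: int = 6,
    gap: int = 5,
) -> tuple[Corpus, dict[str, int]]:
    """A corpus with planted token blocks and adversarial within-sentence order.

    Each sentence draws its tokens predominantly from one block, but
    consecutive block tokens are separated by ``gap`` uniform background
    tokens — farther apart than a window of the same size reaches — so an
    unshuffled window-limited trainer sees block tokens co-occur only with
    noise, while shuffling lets them meet. Returns the corpus and a map
    token -> block index (background tokens map to -1).
    """
    if min(n_blocks, tokens_per_block, n_sentences, n_noise_tokens) < 1 or gap < 0:
        raise SpecError("all planted-block parameters must be positive")
    rng = np.random.default_rng(seed)
    blocks = [
        [f"blk{b}_tok{t:02d}" for t in range(tokens_per_block)]
        for b in range(n_blocks)
    ]
    noise = [f"noise{t:03d}" for t in range(n_noise_tokens)]
    sentences = []
    for _ in range(n_sentences):
        b = int(rng.integers(n_blocks))
        chosen = rng.choice(tokens_per_block,
                            size=min(block_tokens_per_sentence, tokens_per_block),
                            replace=False)
        sent: list[str] = []
        for t in chosen:
            sent.append(blocks[b][t])
            sent.extend(str(x) for x in rng.choice(noise, size=gap, replace=True))
        sentences.append(sent)
    block_map = {tok: b for b, toks in enumerate(blocks) for tok in toks}
    block_map.update({tok: -1 for tok in noise})
    return build_corpus(sentences), block_map
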