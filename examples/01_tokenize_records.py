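"""Discretize raw patient records into medical-concept sentences.

Builds a three-feature schema, tokenizes two admissions, and shows how
continuous values (age, a lab with a reference range, a quartile-binned
resource feature) become discrete concepts while outcome fields stay out.
"""

from emr2vec import (
    Category,
    FeatureSpec,
    PatientRecord,
    Schema,
    ValueKind,
    record_to_sentence,
)
from emr2vec.discretize import fit_cohort_edges

schema = Schema([
    FeatureSpec("sex", Category.DEMOGRAPHICS),
    FeatureSpec("age", Category.DEMOGRAPHICS, ValueKind.AGE),
    FeatureSpec("icu_hours", Category.RESOURCES, ValueKind.CONTINUOUS_QUARTILE),
    FeatureSpec("glucose", Category.LAB, ValueKind.LAB_REFERENCE,
                reference_range=(3.9, 6.1), n_lab_classes=3),
    FeatureSpec("dx1", Category.DIAGNOSIS),
    FeatureSpec("length_of_stay", Category.OUTCOME),
])

cohort = [
    PatientRecord("p01", {"sex": "male", "age": 64, "icu_hours": 2.0,
                          "glucose": 7.8, "dx1": "I63.9"},
                  outcome={"length_of_stay": 9}),
    PatientRecord("p02", {"sex": "female", "age": 17, "icu_hours": 96.0,
                          "dx1": "I60.9"},
                  outcome={"length_of_stay": 21}),
] + [
    PatientRecord(f"p{i:02d}", {"sex": "male", "icu_hours": float(i)})
    for i in range(3, 11)  # filler admissions so quartile edges can be fitted
]

edges = fit_cohort_edges(cohort, schema)
for rec in cohort[:2]:
    sentence = record_to_sentence(rec, schema, edges)
    print(f"{rec.patient_id}: {' '.join(sentence)}")

# p01: glucose 7.8 is above the 6.1 reference bound -> "high"; age 64 -> ">=60".
# p02: the missing glucose simply contributes no token (no imputation), and
# length_of_stay never appears: outcome fields are excluded from the corpus.
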