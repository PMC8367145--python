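import numpy as np
import pytest

from emr2vec import (
    Category,
    FeatureSpec,
    Schema,
    TrainConfig,
    ValueKind,
    build_corpus,
    default_cohort_spec,
    generate_cohort,
    schema_for,
)


@pytest.fixture(scope="session")
def toy_schema() -> Schema:
    return Schema(
        [
            FeatureSpec("sex", Category.DEMOGRAPHICS),
            FeatureSpec("age", Category.DEMOGRAPHICS, ValueKind.AGE),
            FeatureSpec("admission_type", Category.ADMISSION),
            FeatureSpec("icu_hours", Category.RESOURCES, ValueKind.CONTINUOUS_QUARTILE),
            FeatureSpec("dx1", Category.DIAGNOSIS),
            FeatureSpec(
                "glucose", Category.LAB, ValueKind.LAB_REFERENCE,
                reference_range=(3.9, 6.1), n_lab_classes=3,
            ),
            FeatureSpec(
                "wbc", Category.LAB, ValueKind.LAB_REFERENCE,
                reference_range=(4.0, 10.0), n_lab_classes=2,
            ),
            FeatureSpec("length_of_stay", Category.OUTCOME),
            FeatureSpec("death", Category.OUTCOME),
        ]
    )


@pytest.fixture(scope="session")
def two_pair_corpus():
    """500 sentences [A B] and 500 [C D]: forces cos(A,B) >> cos(A,C)."""
    return build_corpus([["A", "B"]] * 500 + [["C", "D"]] * 500)


@pytest.fixture(scope="session")
def small_cfg() -> TrainConfig:
    return TrainConfig(dim=16, window=5, epochs=5, seed=3, n_shuffles=3)


@pytest.fixture(scope="session")
def small_cohort():
    """400-patient two-class cohort shared across tests (generation is cheap,
    training on it is not, so tests that train use even smaller slices)."""
    spec = default_cohort_spec(400, seed=7)
    records, truth, ledger = generate_cohort(spec)
    return spec, records, truth, ledger, schema_for(spec)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
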