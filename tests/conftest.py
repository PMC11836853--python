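import pytest

from hhpheno import (
    CohortBlueprint,
    aggregate_patients,
    generate,
    select_baseline,
)


@pytest.fixture(scope="session")
def blueprint():
    return CohortBlueprint.default(seed=7)


@pytest.fixture(scope="session")
def cohort(blueprint):
    return generate(blueprint)


@pytest.fixture(scope="session")
def records(cohort):
    return aggregate_patients(select_baseline(cohort.episodes))


@pytest.fixture(scope="session")
def labels(cohort):
    return cohort.labels


@pytest.fixture(scope="session")
def label_map(labels):
    return {l.patient_id: l.category for l in labels}
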