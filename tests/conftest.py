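import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import balfprofiler as bp

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basis() -> bp.ReferenceBasis:
    return bp.generate_reference_basis(seed=11)


@pytest.fixture(scope="session")
def cohort() -> bp.SyntheticCohort:
    """Default-condition synthetic cohort used across discriminant tests."""
    return bp.generate_cohort(bp.GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def labeled_cohort(cohort) -> bp.LabeledCohort:
    return bp.LabeledCohort(
        fingerprints=cohort.fingerprints,
        labels=cohort.labels,
        severity=cohort.severity,
    )


@pytest.fixture(scope="session")
def packaged_cohort():
    return bp.load_packaged_cohort()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
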