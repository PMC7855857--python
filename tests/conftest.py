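import numpy as np
import pytest

from survnet import (
    ArchitectureConfig,
    CohortSchema,
    CovariateSpec,
    PatientRecord,
    SimulationConfig,
    encode_cohort,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_schema():
    return CohortSchema(
        covariates=(
            CovariateSpec(name="age", kind="continuous"),
            CovariateSpec(name="size", kind="continuous"),
            CovariateSpec(name="sex", kind="categorical",
                          codes={"Female": -1, "Male": 1}),
            CovariateSpec(name="grade", kind="categorical",
                          codes={"low": -1, "mid": 1, "high": 2}),
        )
    )


@pytest.fixture
def tiny_records(tiny_schema):
    return [
        PatientRecord(id="a", values=(40.0, 2.0, "Male", "low"), time=12.0, event=1),
        PatientRecord(id="b", values=(60.0, None, "Female", "mid"), time=48.0, event=0),
        PatientRecord(id="c", values=(50.0, 3.0, None, "high"), time=7.5, event=1),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A fully observed encoded cohort with censoring, for network/loss tests."""
    sim = simulate_cohort(
        SimulationConfig(n=120, censor_rate_target=0.5, missing_rate=0.0, seed=7)
    )
    return encode_cohort(sim.records, sim.schema)


@pytest.fixture(scope="session")
def missing_cohort():
    """An encoded cohort with MCAR missingness."""
    sim = simulate_cohort(
        SimulationConfig(n=150, censor_rate_target=0.5, missing_rate=0.25, seed=11)
    )
    return encode_cohort(sim.records, sim.schema)


@pytest.fixture
def default_arch():
    return ArchitectureConfig()
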