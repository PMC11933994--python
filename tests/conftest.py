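import numpy as np
import pytest

from kidneywait import (
    REGISTRY_2022,
    calibrate_to_registry,
    generate_parameter_set,
    make_initial_occupancy,
    run_model,
)
from kidneywait.report import RunConfig, run_suite
from kidneywait.synthetic import default_cohort_spec, microsimulate

SEED = 1


@pytest.fixture(scope="session")
def cohort_spec():
    return default_cohort_spec()


@pytest.fixture(scope="session")
def registry_params():
    return generate_parameter_set(SEED, "registry2022")


@pytest.fixture(scope="session")
def calibrated(cohort_spec, registry_params):
    return calibrate_to_registry(REGISTRY_2022, cohort_spec, registry_params)


@pytest.fixture(scope="session")
def status_quo_trace(cohort_spec, calibrated):
    occ0 = make_initial_occupancy(cohort_spec, 1.0)
    return run_model(occ0, calibrated.params, horizon=120)


@pytest.fixture(scope="session")
def microsim_result(cohort_spec, calibrated):
    return microsimulate(calibrated.params, cohort_spec, n=50_000, seed=7)


@pytest.fixture(scope="session")
def full_bundle():
    """Calibrated 19-scenario run over the full 10-year horizon."""
    return run_suite(RunConfig(seed=SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
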