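import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from polyclone.simulate import SimParams, simulate_patient


@pytest.fixture(scope="session")
def clean_params():
    """Error-free, artifact-free, all-clonal study conditions."""
    return SimParams(
        error_rate=0.0,
        strand_bias_artifact_rate=0.0,
        read_end_artifact_rate=0.0,
        fraction_subclonal=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def clean_patient(clean_params):
    return simulate_patient(clean_params, 0)


@pytest.fixture(scope="session")
def noisy_params():
    """Default study conditions: 1e-3 error, both artifact classes."""
    return SimParams(seed=1)


@pytest.fixture(scope="session")
def noisy_patient(noisy_params):
    return simulate_patient(noisy_params, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
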