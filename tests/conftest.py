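import numpy as np
import pytest

from blockplan.records import DurationSample
from blockplan.synth import (
    CSE_N,
    CSE_TARGETS,
    SPINAL_N,
    SPINAL_TARGETS,
    calibrate_mixture,
    sample_durations,
)


@pytest.fixture(scope="session")
def spinal_params():
    return calibrate_mixture(SPINAL_TARGETS)


@pytest.fixture(scope="session")
def cse_params():
    return calibrate_mixture(CSE_TARGETS)


@pytest.fixture(scope="session")
def spinal_sample(spinal_params) -> DurationSample:
    """Seeded stand-in for the published empirical spinal sample."""
    return sample_durations(spinal_params, SPINAL_N, seed=101)


@pytest.fixture(scope="session")
def cse_sample(cse_params) -> DurationSample:
    return sample_durations(cse_params, CSE_N, seed=102, block_type="cse")


@pytest.fixture
def tiny_sample() -> DurationSample:
    rng = np.random.default_rng(7)
    return DurationSample("spinal", rng.lognormal(2.1, 0.4, 500))
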