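import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from arousalpipe.montage import load_montage
from arousalpipe.synthetic import CohortConfig


@pytest.fixture(scope="session")
def montage64():
    return load_montage(64)


@pytest.fixture(scope="session")
def montage24():
    return load_montage(24)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def exp1_config():
    return CohortConfig(experiment="exp1", seed=7, n_participants=2)


@pytest.fixture(scope="session")
def exp2_config():
    return CohortConfig(experiment="exp2", seed=7, n_participants=2)


@pytest.fixture(scope="session")
def exp3_config():
    return CohortConfig(experiment="exp3", seed=7, n_participants=2)


@pytest.fixture(scope="session")
def freqs45():
    return np.arange(1.0, 46.0)
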