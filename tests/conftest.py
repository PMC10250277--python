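import numpy as np
import pytest

from planscope import (
    ObservationModel,
    build_environment,
    default_feature_bank,
    default_registry,
)


@pytest.fixture(scope="session")
def env3():
    return build_environment("increasing_variance_3step")


@pytest.fixture(scope="session")
def env5():
    return build_environment("increasing_variance_5step")


@pytest.fixture(scope="session")
def registry3(env3):
    return default_registry(env3)


@pytest.fixture(scope="session")
def bank3(env3):
    return default_feature_bank(env3)


@pytest.fixture(scope="session")
def obs3(env3, registry3, bank3):
    """Observation model with weights fitted once for the whole session."""
    return ObservationModel(env3, registry3, bank3).fit(n_sim=300, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
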