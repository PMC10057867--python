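import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pollenoptics import ContaminationModel, InstrumentConfig, builtin_profiles

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cfg() -> InstrumentConfig:
    return InstrumentConfig()


@pytest.fixture(scope="session")
def registry():
    return builtin_profiles()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean() -> ContaminationModel:
    return ContaminationModel.none()
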