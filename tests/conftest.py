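import numpy as np
import pytest

from gammacc.montage import build_layout, derive_bipolar
from gammacc.synth import GeneratorParams, StimulusCondition, SubjectProfile


@pytest.fixture(scope="session")
def layout():
    return build_layout()


@pytest.fixture(scope="session")
def montage(layout):
    return derive_bipolar(layout)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def healthy_subject():
    return SubjectProfile("h000", 70, "male", "healthy", 0.0)


@pytest.fixture
def mci_subject():
    return SubjectProfile("m000", 70, "male", "MCI", 0.5)


@pytest.fixture
def static_condition():
    return StimulusCondition(2, 0, 0)


@pytest.fixture
def oz_params():
    """Single-channel generator setup for spectral-statistics tests."""
    return GeneratorParams(channels=("Oz",), artifact_rate=0.0)
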