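import numpy as np
import pytest

from alloego import Canvas, TrialSpec


@pytest.fixture
def canvas200() -> Canvas:
    return Canvas(200, 100.0)


@pytest.fixture
def canvas64() -> Canvas:
    return Canvas(64, 100.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def simple_trial() -> TrialSpec:
    return TrialSpec(target=[30.0, 30.0], landmark=[0.0, 0.0],
                     shift=[0.0, 0.0], initial_gaze=[0.0, 0.0],
                     final_gaze=[30.0, 30.0])
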