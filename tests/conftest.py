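import numpy as np
import pytest

from aquabudget import TrialConfig, trial_diets


@pytest.fixture
def diets():
    return trial_diets()


@pytest.fixture
def default_config():
    return TrialConfig(seed=12345)


@pytest.fixture
def noise_free_config():
    return TrialConfig(seed=12345, measurement_cv=0.0, initial_weight_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240709)
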