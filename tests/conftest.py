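import numpy as np
import pandas as pd
import pytest

from ashcarbon.core import default_treatments
from ashcarbon.synthetic import SimulationConfig, generate_incubation


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def noisefree_dataset():
    return generate_incubation(SimulationConfig(seed=7).zero_noise())


@pytest.fixture(scope="session")
def noisy_dataset(default_config):
    return generate_incubation(default_config)


@pytest.fixture(scope="session")
def treatments_by_code():
    return {t.code: t for t in default_treatments()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
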