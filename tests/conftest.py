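import numpy as np
import pytest

from protoncea.mortality import LifeTable
from protoncea.params import default_params
from protoncea.synthetic import bundled_life_table


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def life_table():
    return bundled_life_table()


@pytest.fixture(scope="session")
def zero_life_table():
    return LifeTable(np.zeros(101))


@pytest.fixture(scope="session")
def flat_life_table():
    return LifeTable(np.full(101, 0.02))
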