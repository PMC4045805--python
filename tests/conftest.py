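import numpy as np
import pytest

from amirproc import make_fixtures, make_hairpin
from amirproc.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures()


@pytest.fixture(scope="session")
def sim_hairpin():
    return make_hairpin(arm_len=95, loop_len=14, seed=11)


@pytest.fixture()
def sim_config(sim_hairpin):
    return SimulationConfig(hairpin=sim_hairpin, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
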