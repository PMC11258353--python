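import numpy as np
import pytest

from gbas.kinetics import LigandDose
from gbas.synthetic_data import (
    SimConfig,
    electrode_gdh5e_plus,
    electrode_gdh_wt,
    solution_gdh5e_plus,
    solution_gdh_wt,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def e5_solution():
    return solution_gdh5e_plus()


@pytest.fixture(scope="session")
def ewt_solution():
    return solution_gdh_wt()


@pytest.fixture(scope="session")
def e5_electrode():
    return electrode_gdh5e_plus()


@pytest.fixture(scope="session")
def ewt_electrode():
    return electrode_gdh_wt()


@pytest.fixture
def blank_dose():
    return LigandDose("none", 0.0, 0.01)


@pytest.fixture
def ht_1nM():
    return LigandDose("4-HT", 1e-9, 0.01)


@pytest.fixture
def ht_1uM():
    return LigandDose("4-HT", 1e-6, 0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
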