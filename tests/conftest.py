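import numpy as np
import pytest

from ifniche.containers import GeneSet
from ifniche.lattice import build_adjacency, full_hex_lattice
from ifniche.simulate import SimulationConfig, make_lattice_sample


@pytest.fixture(scope="session")
def small_lattice():
    return full_hex_lattice(9, 9)


@pytest.fixture(scope="session")
def small_graph(small_lattice):
    return build_adjacency(small_lattice)


@pytest.fixture(scope="session")
def study_config():
    """Default study conditions: ~3,000-spot section, BZ colonies."""
    return SimulationConfig(seed=11, n_colonies=3)


@pytest.fixture(scope="session")
def study_sample(study_config):
    return make_lattice_sample(study_config)


@pytest.fixture()
def isg_set(study_config):
    return GeneSet("ISG score", list(study_config.isg_genes), "ISG")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
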