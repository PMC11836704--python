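import numpy as np
import pytest

from seedsmr.simulate import SimulationConfig, simulate_tree


@pytest.fixture(scope="session")
def three_taxon_tree():
    from seedsmr.trees import Phylogeny

    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def medium_tree():
    """A 50-tip ultrametric birth-death tree reused across tests."""
    return simulate_tree(SimulationConfig(n_species=50), seed=424242)


@pytest.fixture
def rng():
    return np.random.default_rng(20259)
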