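import numpy as np
import pytest

from sawselect.synthetic import (
    CodonModelParams,
    SimulationConfig,
    simulate_codon_alignment,
)
from sawselect.trees import SpeciesTree


@pytest.fixture(scope="session")
def five_taxon_tree() -> SpeciesTree:
    return SpeciesTree.default_five_taxon()


@pytest.fixture(scope="session")
def small_alignment(five_taxon_tree):
    """A 120-codon neutral-background alignment shared by fast tests."""
    cfg = SimulationConfig(
        tree=five_taxon_tree, params=CodonModelParams(), n_sites=120, seed=7
    )
    return simulate_codon_alignment(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
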