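import numpy as np
import pytest
from hypothesis import settings

from convrates.design import DEFAULT_DESIGN, PairDesign
from convrates.simulate import SimParams, SimTree, simulate_codon_alignment

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design() -> PairDesign:
    return DEFAULT_DESIGN


@pytest.fixture(scope="session")
def default_tree() -> SimTree:
    return SimTree()


@pytest.fixture(scope="session")
def small_codon_sim(default_tree, design):
    """20 genes x 350 codons with 6 planted convergent sites."""
    params = SimParams(seed=101, n_genes=20, gene_length=350, n_convergent_sites=6)
    return simulate_codon_alignment(default_tree, params, design)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
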