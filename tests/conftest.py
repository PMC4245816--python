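import numpy as np
import pytest

from edcscan import PipelineConfig, generate_locus


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_locus():
    """A small synthetic locus shared across tests (8 genes, 20 decoys)."""
    scaffold, truth = generate_locus(n_genes=8, n_decoys=20, seed=5)
    return scaffold, truth


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
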