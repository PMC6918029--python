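import numpy as np
import pytest

from phagekit.simulate import generate_family, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(n_genes=15, mean_gene_len=120, gc=0.45, seed=11, genome_id="G1")


@pytest.fixture(scope="session")
def family_three():
    """A parent and two children at divergence 0.15."""
    return generate_family(
        3, n_genes=15, aa_divergence=0.15, gene_loss=0.0, gene_gain=0,
        mean_gene_len=120, seed=21, group="famX",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
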