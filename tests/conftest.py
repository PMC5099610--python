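import numpy as np
import pytest

from bacpool.config import GenomeConfig
from bacpool.genome import generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 150 kb ground-truthed genome shared by read-level tests."""
    return generate_genome(
        GenomeConfig(length_bp=150_000, n_markers=6, n_genes=5, n_snps=4), seed=21
    )


@pytest.fixture(scope="session")
def midsize_genome():
    """A 500 kb genome for library/physical-map statistics."""
    return generate_genome(GenomeConfig(length_bp=500_000, n_genes=13), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
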