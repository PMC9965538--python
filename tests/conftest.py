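import numpy as np
import pytest

from phagetax.simulate import GenomeSpec, synthesize_phage_genome


@pytest.fixture(scope="session")
def default_genome():
    """One full-size synthetic genome with planted features (seed 1)."""
    return synthesize_phage_genome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def small_genome():
    """A 20 kb genome for alignment-heavy tests."""
    return synthesize_phage_genome(GenomeSpec(length=20000, n_genes=25, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n, gc=0.42):
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])
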