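import numpy as np
import pytest

from intronsig.genome_io import GeneModel
from intronsig.synthetic_data import SimulationParams, simulate_genome


@pytest.fixture(scope="session")
def small_dataset():
    """A 120-gene synthetic dataset shared by read-only tests."""
    return simulate_genome(SimulationParams(n_genes=120, seed=42))


@pytest.fixture()
def plus_gene():
    # two exons [0,10) and [20,30) around intron [10,20)
    return GeneModel("gp", "c1", "+", [(0, 10), (20, 30)], expression=5.0)


@pytest.fixture()
def minus_gene():
    return GeneModel("gm", "c1", "-", [(0, 10), (20, 30)], expression=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
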