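import numpy as np
import pytest

from splitjunc import generate_genome


@pytest.fixture(scope="session")
def genome():
    """Small two-chromosome genome with a circular mito contig and 20 genes."""
    return generate_genome([100_000, 80_000], gc_fraction=0.40,
                           mito_length=20_000, n_genes=20, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
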