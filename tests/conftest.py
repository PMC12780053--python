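import numpy as np
import pytest

import fgcnmf as f


@pytest.fixture(scope="session")
def desk_dataset():
    """Planted-block dataset at desk scale: 100 microbes x 30 diseases,
    5 blocks, strong in-block link signal."""
    spec = f.SyntheticSpec(100, 30, 5, 0.3, 0.01, seed=7)
    sim_m, sim_d, MD = f.generate(spec)
    return f.Dataset(sim_m, sim_d, MD)


@pytest.fixture(scope="session")
def small_network():
    """A 30+12-node heterogeneous network with edges in every block."""
    spec = f.SyntheticSpec(30, 12, 3, 0.5, 0.05, seed=5)
    sim_m, sim_d, MD = f.generate(spec)
    SM = f.sparsify_topn(sim_m, 3)
    SD = f.sparsify_topn(sim_d, 3)
    return f.assemble_network(SM, SD, MD)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
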