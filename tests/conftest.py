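import numpy as np
import pytest

import scdrl


@pytest.fixture(scope="session")
def tiny_sim():
    """One shared tiny simulation: 2000 cells, 200 genes, 8 cell types."""
    return scdrl.simulate(scdrl.tiny_config(seed=0))


@pytest.fixture(scope="session")
def tiny_lognorm(tiny_sim):
    return scdrl.normalize(tiny_sim.dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """Two binary factors + one 3-category factor, residual dim 4."""
    return scdrl.FactorSpec.build(
        [("batch", ["b0", "b1"]),
         ("condition", ["ctrl", "stim"]),
         ("cell_type", ["t0", "t1", "t2"])],
        residual_dim=4,
    )
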