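import numpy as np
import pytest

from riboshift import SimConfig, simulate_gene


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def sim_config():
    return SimConfig(seed=0)


@pytest.fixture
def ty1_gene():
    """One deterministic simulated Ty1-type frameshift gene (sequence, model)."""
    return simulate_gene(SimConfig(seed=42))
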