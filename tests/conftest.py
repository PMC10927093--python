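import numpy as np
import pytest

from apakit.config import SimConfig
from apakit.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """30 genes, 6 shortened, jitter 0, with planted internal-priming
    artifacts — shared by several module tests (read-only)."""
    cfg = SimConfig(n_genes=30, n_shortened=6, seed=11, depth_per_gene=500,
                    ip_artifact_rate=0.2, cleavage_jitter_sd=0.0)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(202409)
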