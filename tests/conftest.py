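import numpy as np
import pytest

from isote import SimConfig, run_pipeline, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20160718)


@pytest.fixture(scope="session")
def small_dataset():
    """Thirty genes with default study conditions, shared across tests."""
    return simulate_dataset(SimConfig(n_genes=30, seed=1))


@pytest.fixture(scope="session")
def pipeline_result(small_dataset):
    return run_pipeline(small_dataset, n_boot=200, seed=2, fold_step=10,
                        n_shuffles=20)
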