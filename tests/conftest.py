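import numpy as np
import pytest

from spotmix.data import ExpressionMatrix, Hyperparameters, MarkerMatrix
from spotmix.simulate import ScenarioConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def toy_problem(rng):
    """3 genes x 4 spots x 2 types (second type dummy): small enough for
    brute-force joint-density oracles."""
    counts = rng.poisson(5.0, size=(3, 4))
    data = ExpressionMatrix(counts, [f"g{i}" for i in range(3)], [f"s{j}" for j in range(4)])
    B = MarkerMatrix(np.array([[1, 0], [1, 0], [1, 0]]), data.gene_ids,
                     ["typeA", "dummy"], dummy_index=1)
    hyper = Hyperparameters(alpha=3.0, l=np.full(4, 8.0), sigma=2.0)
    return data, B, hyper


@pytest.fixture(scope="session")
def small_dataset():
    """One 40-spot sparse replicate with known truth, reused across tests."""
    return simulate_dataset(ScenarioConfig(s_M=40, density="sparse", seed=424242))
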