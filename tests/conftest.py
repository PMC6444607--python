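import numpy as np
import pytest

from adlasso import (
    SimulationConfig,
    center_phenotype,
    one_hot_encode,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated dataset reused across tests (n=200, p=80)."""
    cfg = SimulationConfig(
        n_individuals=200, n_snps=80, n_random_qtl=5, seed=11, test_fraction=0.3
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_encoded(small_dataset):
    """Encoded train/test arrays for the small dataset."""
    ds = small_dataset
    X = one_hot_encode(ds.genotypes)
    tr, te = ds.split.repeats[0]
    pv = center_phenotype(ds.phenotypes[tr])
    return {
        "design": X,
        "X_train": X.values[tr],
        "y_train": pv.values,
        "X_test": X.values[te],
        "y_test": ds.phenotypes[te] - pv.training_mean,
        "training_mean": pv.training_mean,
        "dataset": ds,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(123)
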