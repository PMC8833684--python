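import numpy as np
import pytest

from efsbench.classify import CVScheme
from efsbench.synthetic import paper_shape_config, planted_config, simulate_dataset


@pytest.fixture(scope="session")
def study_dataset():
    """Study-shaped synthetic cohort: 252 x 120, nested labels, seed 0."""
    return simulate_dataset(paper_shape_config(0))


@pytest.fixture(scope="session")
def study_table(study_dataset):
    return study_dataset[0]


@pytest.fixture(scope="session")
def study_labels(study_dataset):
    return study_dataset[1]


@pytest.fixture(scope="session")
def small_planted():
    """d=20 independent features, one informative (the last), n=150."""
    table, labels = simulate_dataset(
        planted_config(20, 1, n_samples=150, seed=6)
    )
    return table, labels.task("pathologic")


@pytest.fixture
def cv5():
    return CVScheme(5, True, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
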