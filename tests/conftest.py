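import numpy as np
import pytest

from swarmbalance.pipeline import ClassifierConfig
from swarmbalance.rebalance import LabeledDataset
from swarmbalance.swarm_mo import SwarmConfig
from swarmbalance.synthdata import FIXTURE_SPECS, generate


@pytest.fixture(scope="session")
def easy():
    dataset, truth = generate(FIXTURE_SPECS["easy"])
    return dataset, truth


@pytest.fixture(scope="session")
def hard():
    dataset, truth = generate(FIXTURE_SPECS["hard"])
    return dataset, truth


@pytest.fixture(scope="session")
def clf_config():
    return ClassifierConfig(seed=0)


@pytest.fixture
def small_swarm():
    """Desk-scale swarm settings for unit tests."""
    return SwarmConfig(population=5, max_iterations=8, seed=3)


def two_blob_dataset(n_majority=100, n_minority=10, separation=12.0, seed=0) -> LabeledDataset:
    """Linearly separable toy: one majority blob, one distant minority blob."""
    rng = np.random.default_rng(seed)
    maj = rng.standard_normal((n_majority, 2))
    mino = rng.standard_normal((n_minority, 2)) + separation
    return LabeledDataset(
        features=np.vstack([maj, mino]),
        labels=np.array([0] * n_majority + [1] * n_minority),
        minority_label=1,
    )


@pytest.fixture
def separable():
    return two_blob_dataset()
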