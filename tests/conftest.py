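"""Shared fixtures: seeded synthetic datasets and trained likelihood models."""

import numpy as np
import pytest

from gaitbayes import evaluate as ev
from gaitbayes import simulator as sim


@pytest.fixture(scope="session")
def train_dataset():
    """One trial of each ambulation direction (covers all 56 classes)."""
    return sim.concat_datasets(
        sim.generate_dataset(sim.ProtocolSpec(direction=d, seed=s))
        for d, s in [(1, 11), (2, 12)]
    )


@pytest.fixture(scope="session")
def models(train_dataset):
    return ev.train_models(train_dataset)


@pytest.fixture(scope="session")
def eval_dataset():
    """A held-out direction-1 trial from the same emission model."""
    return sim.generate_dataset(sim.ProtocolSpec(direction=1, seed=99))


@pytest.fixture(scope="session")
def replay_pair(eval_dataset, models):
    """(fc, ber-fc) replay results on the same held-out trial."""
    return {
        mode: ev.replay(eval_dataset, models, mode=mode)
        for mode in ("fc", "ber-fc")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240427)
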