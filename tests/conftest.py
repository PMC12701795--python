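import numpy as np
import pytest

from rnacodesign.pipeline import TrainingConfig, default_sdfe, train
from rnacodesign.synthetic_data import (GeneratorConfig, generate_dataset,
                                        similarity_split)


@pytest.fixture(scope="session")
def sdfe():
    return default_sdfe(seed=0)


@pytest.fixture(scope="session")
def small_split():
    dataset = generate_dataset(GeneratorConfig(n_complexes=20, seed=3))
    return similarity_split(dataset, seed=0)


@pytest.fixture(scope="session")
def trained_models(small_split, sdfe):
    """A modestly trained model pair shared across tests (~2 s to build)."""
    config = TrainingConfig(epochs=100, seed=0, learning_rate=0.02)
    seq_model, struct_model, log = train(small_split.train, small_split.val,
                                         config, sdfe=sdfe)
    return seq_model, struct_model, log


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
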