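import numpy as np
import pytest

from semgnn.chemio import Molecule3D, embed_3d
from semgnn.mignn import ModelConfig
from semgnn.synthetic import SyntheticSpec, build_library, generate_dataset
from semgnn.training import random_split, train_model


@pytest.fixture(scope="session")
def library():
    return build_library(0)


@pytest.fixture(scope="session")
def tiny_dataset(library):
    """96 reactions with a planted steric-only response."""
    spec = SyntheticSpec(n_reactions=96, noise_sd=2.0, seed=0)
    return generate_dataset(spec, library)


@pytest.fixture(scope="session")
def tiny_trained(tiny_dataset):
    """A briefly trained model for interpretation/contract tests."""
    records, _ = tiny_dataset
    train, test = random_split(records, 0.75, 0)
    cfg = ModelConfig(epochs=6, batch_size=32, seed=0, learning_rate=3e-3)
    trained = train_model(train, val_fraction=0.1, cfg=cfg)
    return trained, train, test


@pytest.fixture()
def water():
    return embed_3d("O", seed=0)


@pytest.fixture()
def methane():
    return embed_3d("C", seed=0)


@pytest.fixture()
def isolated_cl():
    return Molecule3D(["Cl"], np.zeros((1, 3)))
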