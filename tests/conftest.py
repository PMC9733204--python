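import numpy as np
import pytest

import stackcvae as sc
from stackcvae.generative_model import ModelConfig, pretrain

# Small architecture used throughout the tests: the full-size defaults
# (512 hidden units, 3 layers) are exercised only for shape/config checks.
TOY_CONFIG = dict(hidden_size=32, num_layers=1, stack_width=8, stack_depth=5,
                  latent_dim=16, embedding_dim=16, max_len=60, batch_size=64,
                  learning_rate=3e-3)

SORAFENIB = "CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1"


@pytest.fixture(scope="session")
def toy_corpus():
    return sc.generate_toy_corpus(500, seed=7)


@pytest.fixture(scope="session")
def filtered_corpus(toy_corpus):
    return sc.filter_corpus(toy_corpus)


@pytest.fixture(scope="session")
def toy_config():
    return ModelConfig(**TOY_CONFIG)


@pytest.fixture(scope="session")
def pretrained(filtered_corpus, toy_config):
    """Session-scoped toy pretraining run shared by the heavier tests."""
    model, curve = pretrain(filtered_corpus, toy_config, seed=1, epochs=30)
    return model, curve


@pytest.fixture
def rng():
    return np.random.default_rng(0)
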