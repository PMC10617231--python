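import numpy as np
import pytest

from pepfunc import (DEFAULT_FUNCTIONS, FunctionVocabulary,
                     LabelEmbeddingTransformer, ModelConfig, TrainingConfig)
from pepfunc.synthetic import SyntheticSpec, make_benchmark


@pytest.fixture(scope="session")
def vocab4():
    return FunctionVocabulary(DEFAULT_FUNCTIONS[:4])


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(C=4, d_model=16, n_heads=2, d_ff=32, L=50)


@pytest.fixture()
def tiny_model(tiny_model_config, vocab4):
    return LabelEmbeddingTransformer(tiny_model_config, vocab4, seed=0)


@pytest.fixture(scope="session")
def tiny_bench():
    """A small learnable benchmark: 4 functions, 160 samples, short epochs."""
    spec = SyntheticSpec(C=4, n_samples=160, seed=7)
    return make_benchmark(spec)


@pytest.fixture(scope="session")
def tiny_train_config():
    return TrainingConfig(epochs=2, phase2_epochs=2, batch_size=16,
                          warmup_steps=20, seeds=(0, 1))


def rand_label_pair(rng, n=20, c=5):
    return (rng.integers(0, 2, size=(n, c)), rng.integers(0, 2, size=(n, c)))
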