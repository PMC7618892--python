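import numpy as np
import pytest

from denovoms import ResidueVocabulary
from denovoms.model import ModelConfig, train_model
from denovoms.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def vocab():
    return ResidueVocabulary.default()


@pytest.fixture(scope="session")
def clean_psms(vocab):
    """A small noise-free synthetic dataset shared across unit tests."""
    cfg = SimulationConfig.clean(n_peptides=40, length_range=(6, 10), seed=7)
    return generate_dataset(cfg, vocab)


@pytest.fixture(scope="session")
def overfit_model(vocab, clean_psms):
    """A toy model overfit on the small clean dataset (training sanity)."""
    cfg = ModelConfig.toy()
    model, trace = train_model(
        clean_psms, cfg, epochs=60, seed=0, batch_size=20, lr=2e-3
    )
    return model, trace
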