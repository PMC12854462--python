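import logging

import numpy as np
import pytest

from stcontrast import RunConfig, TissueSpec, make_tissue
from stcontrast.config import PolicyConfig
from stcontrast.model_core import ModelConfig

logging.getLogger("stcontrast").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_tissue():
    """Small 3-band tissue used across unit tests (225 spots, 100 genes)."""
    return make_tissue(TissueSpec(n_side=15, K=3, n_genes=100, seed=7))


@pytest.fixture(scope="session")
def tiny_config():
    return RunConfig(
        n_domains=3,
        epochs=2,
        seed=7,
        model=ModelConfig(batch_size=128, d=32, decoder_hidden=64),
        policy=PolicyConfig(n_candidates=2),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
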