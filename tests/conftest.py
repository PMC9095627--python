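import numpy as np
import pytest

from persist.config import load_default_config
from persist.model import ModelParams
from persist.registry import default_registry
from persist.synthetic import SpectralModel, UptakeModel


@pytest.fixture(scope="session")
def cfg():
    return load_default_config()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def params(cfg):
    return ModelParams.from_config(cfg)


@pytest.fixture(scope="session")
def spectral(cfg):
    return SpectralModel.from_config(cfg)


@pytest.fixture(scope="session")
def uptake(cfg):
    return UptakeModel.from_config(cfg)


@pytest.fixture(scope="session")
def comp_ctx(cfg):
    """One compensation context shared across tests (controls are slow-ish)."""
    from persist.experiments import make_compensation

    return make_compensation(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
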