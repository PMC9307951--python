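import numpy as np
import pytest

from tauquant.isoforms import load_default_registry


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def canonical(registry):
    return registry.canonical


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
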