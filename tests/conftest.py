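import numpy as np
import pytest

from protonrv.materials import default_registry
from protonrv.phantom import build_rect_phantom
from protonrv.transport import TransportConfig


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def water(registry):
    return registry["water"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse water block sized for a 120 MeV beam (CSDA ~10.7 cm)."""
    return build_rect_phantom((15.0, 10.0, 10.0), 5.0)


@pytest.fixture()
def fast_transport():
    return TransportConfig()
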