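import numpy as np
import pytest

from mitoflim import ProbeModel, TCSPCConfig, gaussian_irf


@pytest.fixture(scope="session")
def cfg():
    """Default acquisition: 80 MHz, 256 bins over 12.5 ns, 0.25 ns FWHM IRF."""
    return TCSPCConfig()


@pytest.fixture(scope="session")
def irf(cfg):
    return gaussian_irf(cfg)


@pytest.fixture(scope="session")
def probe():
    """Default probe: 1.5 -> 0.2 ns dynamic range, half-quenching at 20 µM."""
    return ProbeModel()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
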