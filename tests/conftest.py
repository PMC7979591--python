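import numpy as np
import pytest

from liveriron.signal import FatSpectrum, load_protocol


@pytest.fixture(scope="session")
def spectrum():
    return FatSpectrum.default()


@pytest.fixture(scope="session")
def megre():
    return load_protocol("me-gre")


@pytest.fixture(scope="session")
def qdixon():
    return load_protocol("qdixon")


@pytest.fixture(scope="session")
def wip():
    return load_protocol("qdixon-wip")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def rice_draw(nu, sigma, rng):
    """Independent Rice sampler used by simulation-based tests."""
    nu = np.asarray(nu, dtype=float)
    return np.hypot(nu + sigma * rng.standard_normal(nu.shape),
                    sigma * rng.standard_normal(nu.shape))
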