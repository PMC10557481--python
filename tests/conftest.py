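import numpy as np
import pytest

import riciantv as rtv


@pytest.fixture(scope="session")
def suite():
    return dict(rtv.standard_suite())


@pytest.fixture(scope="session")
def flat_disks_64(suite):
    """Clean piecewise-constant phantom with its masks."""
    return rtv.make_phantom(suite["flat+disks-64"])


@pytest.fixture(scope="session")
def noisy_pair_64(flat_disks_64):
    """(clean, sigma=15 Rician-corrupted) pair on the 64x64 phantom."""
    clean, _, _ = flat_disks_64
    noisy = rtv.add_rician_noise(clean, rtv.NoiseModel(sigma=15.0, seed=1))
    return clean, noisy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
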