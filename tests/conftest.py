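import numpy as np
import pytest

import diauxkit as dk


@pytest.fixture(scope="session")
def zed():
    """Ancestor-like diauxic genotype (defaults)."""
    return dk.GenotypeParams()


@pytest.fixture(scope="session")
def coutilizer():
    return dk.GenotypeParams(coutilizer=True, mu_co=0.35)


@pytest.fixture(scope="session")
def no_noise():
    return dk.NoiseModel.none()


@pytest.fixture(scope="session")
def clean_batch(zed, no_noise):
    """Noiseless diauxic batch simulation under default conditions."""
    return dk.simulate_batch(zed, noise=no_noise)


@pytest.fixture(scope="session")
def clean_curve(clean_batch):
    return dk.GrowthCurve(clean_batch.time_h, clean_batch.od, well="A1",
                          strain="ZED")


def make_exponential(mu=0.7, od0=0.01, hours=10.0, dt=1 / 6):
    t = np.arange(0.0, hours + 1e-9, dt)
    return t, od0 * np.exp(mu * t)
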