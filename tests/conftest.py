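import numpy as np
import pytest

from ribpet.config import load_config
from ribpet.phantom_beam import SPECIES, skull_phantom, water_phantom


@pytest.fixture(scope="session")
def water():
    return water_phantom(250.0)


@pytest.fixture(scope="session")
def skull():
    return skull_phantom()


@pytest.fixture(scope="session")
def c12():
    return SPECIES["C12"]


@pytest.fixture(scope="session")
def default_config():
    return load_config()


@pytest.fixture(scope="session")
def designed_sobp(default_config, skull):
    """Optimized C12 SOBP on the skull phantom (shared; expensive-ish)."""
    from ribpet.study import _design_sobp

    plan = default_config.plan()
    profiles, beam = _design_sobp(default_config, "C12", skull, plan, 0)
    return profiles, beam, plan


def lognormal_spectrum(median=20.0, sigma=0.6, n=2001, span=6.0):
    """Analytic log-normal f(y) tabulated on a fine log grid."""
    from ribpet.microdosimetry import LinealEnergySpectrum

    mu = np.log(median)
    y = np.geomspace(np.exp(mu - span * sigma), np.exp(mu + span * sigma), n)
    f = np.exp(-0.5 * ((np.log(y) - mu) / sigma) ** 2) / (y * sigma * np.sqrt(2 * np.pi))
    return LinealEnergySpectrum(y, f)
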