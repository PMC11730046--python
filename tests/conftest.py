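import numpy as np
import pytest

from bromolb import PhantomParams, generate_phantom


def make_params(**kw) -> PhantomParams:
    return PhantomParams(**kw)


@pytest.fixture(scope="session")
def homogeneous_case():
    """Uniform -750 HU lung: no noise, no gradients, no clusters."""
    p = PhantomParams(seed=11, normal_sd_hu=0.0, vertical_gradient_hu_per_cm=0.0,
                      radial_gradient_hu=0.0, n_emphysema_clusters=0)
    return generate_phantom(p)


@pytest.fixture(scope="session")
def gradient_case():
    """Noise-free phantom with the vertical (gravity) gradient only."""
    p = PhantomParams(seed=12, normal_sd_hu=0.0, radial_gradient_hu=0.0,
                      n_emphysema_clusters=0)
    return generate_phantom(p)


@pytest.fixture(scope="session")
def onroute_case():
    """Noise-free vertical-gradient phantom with a cluster on the needle corridor."""
    p = PhantomParams(seed=13, normal_sd_hu=0.0, radial_gradient_hu=0.0,
                      emphysema_placement="on_route", n_emphysema_clusters=2)
    return generate_phantom(p)


@pytest.fixture(scope="session")
def offroute_case():
    """Noise-free vertical-gradient phantom with clusters only off the corridor."""
    p = PhantomParams(seed=14, normal_sd_hu=0.0, radial_gradient_hu=0.0,
                      emphysema_placement="off_route", n_emphysema_clusters=3)
    return generate_phantom(p)


@pytest.fixture(scope="session")
def noisy_case():
    """Default realistic phantom (20 HU noise, both gradients, random clusters)."""
    return generate_phantom(PhantomParams(seed=15))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
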