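import numpy as np
import pytest

from ricespec import SceneConfig, generate_endmembers, generate_scene
from ricespec.synthetic import stage_defaults


@pytest.fixture(scope="session")
def wavelengths():
    """2 nm grid over 400-900 nm (251 bands), the default scene sampling."""
    return np.arange(400.0, 900.5, 2.0)


@pytest.fixture(scope="session")
def library(wavelengths):
    return generate_endmembers(wavelengths, seed=1)


@pytest.fixture(scope="session")
def noiseless_scene(library):
    """Jointing-stage scene without noise: pixels are exact endmembers."""
    d = stage_defaults("JT")
    cfg = SceneConfig(stage="JT", green_fraction=d["green_fraction"], lnc=d["lnc"],
                      shade_fraction=d["shade_fraction"], noise_sd=0.0, seed=11)
    cube, labels = generate_scene(cfg, library)
    return cfg, cube, labels


@pytest.fixture(scope="session")
def heading_scene(library):
    """Heading-stage scene with panicles, noiseless."""
    cfg = SceneConfig(stage="HD", green_fraction=0.9, lnc=1.9, shade_fraction=0.4,
                      panicle_fraction=0.2, noise_sd=0.0, seed=5)
    cube, labels = generate_scene(cfg, library)
    return cfg, cube, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
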