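import numpy as np
import pytest

from tetracolour.spectra import WAVELENGTH_GRID, ReflectanceSpectrum
from tetracolour.synthetic import SyntheticConfig, make_illuminant, make_toy_visual_system


@pytest.fixture(scope="session")
def toy_cfg():
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def toy_vs(toy_cfg):
    return make_toy_visual_system(toy_cfg)


@pytest.fixture(scope="session")
def flat_illuminant(toy_cfg):
    return make_illuminant(toy_cfg)


@pytest.fixture(scope="session")
def leaf_background():
    r = 0.05 + 0.12 * np.exp(-0.5 * ((WAVELENGTH_GRID - 550.0) / 45.0) ** 2)
    return ReflectanceSpectrum(WAVELENGTH_GRID, r, "leaf")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
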