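import numpy as np
import pytest

from traptamer.geometry import DesignVariant, HelixParams
from traptamer.kinetics import KineticParams
from traptamer.synthetic_data import ScreenConfig, generate_screen


@pytest.fixture(scope="session")
def params():
    return HelixParams()


@pytest.fixture(scope="session")
def design_14_14():
    return DesignVariant(14, 14)


@pytest.fixture(scope="session")
def kparams():
    return KineticParams()


@pytest.fixture(scope="session")
def screen_df():
    """Default synthetic screening plate (seed 1, 3 replicates, CV 2%)."""
    return generate_screen(ScreenConfig())


@pytest.fixture(scope="session")
def screen_df_clean():
    """Noise-free screening plate."""
    return generate_screen(ScreenConfig(noise_cv=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
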