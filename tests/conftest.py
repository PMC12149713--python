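import numpy as np
import pytest
from hypothesis import settings

from habitatpipe import ivim
from habitatpipe.phantom import PhantomSpec, make_phantom, well_separated_habitats

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bscheme():
    return ivim.paper_scheme()


@pytest.fixture(scope="session")
def separated_phantom():
    """Nested-shell phantom with well-separated habitats at SNR 50."""
    spec = PhantomSpec(grid_shape=(20, 20, 12),
                       habitats=well_separated_habitats(),
                       noise_sigma=2.0, seed=1)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def separated_maps(separated_phantom):
    """Fitted IVIM maps of the separated phantom (shared: fitting is the
    slow step)."""
    ph = separated_phantom
    return ivim.fit_volume(ph.signal, ph.mask, ph.bscheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
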