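import numpy as np
import pytest

from chromaseg import phantom, stains


@pytest.fixture(scope="session")
def basis():
    return stains.default_he_basis()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_noiseless_spec():
    """A fast phantom: 3 radius-30 nests on a 480x360 canvas, no noise."""
    return phantom.PhantomSpec(
        width=480, height=360, n_nests=3, nest_radius_range=(30, 30),
        n_distractors=0, noise_sd=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_noiseless_phantom(small_noiseless_spec):
    return phantom.generate_phantom(small_noiseless_spec)
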