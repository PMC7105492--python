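import numpy as np
import pytest

import gliaquant as gq


@pytest.fixture(scope="session")
def noiseless_astro_image():
    return gq.gen_astrocyte_image(gq.ImagingParams(leaflet_vf=0.045, noise_sd=0.0,
                                                   seed=7))


@pytest.fixture(scope="session")
def noiseless_sweeps():
    return gq.gen_astro_sweeps(gq.SweepParams(noise_sd=0.0, n_sweeps=1, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
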