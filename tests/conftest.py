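import logging

import numpy as np
import pytest

from prostamics.dce import ParkerAif
from prostamics.synthetic import PhantomSpec, generate_phantom

logging.getLogger("prostamics").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def aif() -> ParkerAif:
    return ParkerAif()


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    return PhantomSpec(
        grid_shape=(32, 32, 8),
        spacing_mm=(2.0, 2.0, 3.0),
        prostate_radius_mm=(22.0, 18.0, 11.0),
        gtv_radius_mm=6.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec):
    return generate_phantom(tiny_spec)


@pytest.fixture(scope="session")
def zero_noise_phantom(tiny_spec):
    import dataclasses

    spec = dataclasses.replace(tiny_spec, noise_sd_adc=0.0, noise_sd_dce=0.0, seed=5)
    return spec, generate_phantom(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
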