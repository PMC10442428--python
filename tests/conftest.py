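import numpy as np
import pytest

from fddft import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom_spec() -> PhantomSpec:
    """A half-scale head phantom that keeps unit tests fast."""
    return PhantomSpec(
        shape=(120, 120, 16),
        brain_semiaxes=(44.0, 36.0, 10.0),
        lesion_centers=((75.0, 50.0, 8.0),),
        lesion_radii=((11.0, 10.0, 5.0),),
        skull_thickness=6.0,
        csf_thickness=3.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return generate_phantom(small_phantom_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
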