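import numpy as np
import pytest

from hspseg import PhantomSpec, Volume3D, generate_phantom


@pytest.fixture(scope="session")
def phantom_noise_free():
    """Default-geometry phantom with zero noise (deterministic scene)."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, rng_seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20220417)


@pytest.fixture()
def small_volume(rng):
    """Random 15^3 integer-valued volume at the default spacing."""
    data = rng.integers(0, 200, size=(15, 15, 15)).astype(float)
    return Volume3D(data=data, spacing=(0.45, 0.45, 0.9))
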