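import numpy as np
import pytest

from petdti.phantom import PhantomSpec, generate_phantom
from petdti.volume import Volume3D


def centered_affine(shape, spacing=2.0):
    a = np.eye(4)
    a[:3, :3] *= spacing
    a[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * spacing
    return a


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    """Random volume on an even grid whose midline x = 0 is grid-aligned."""
    shape = (12, 10, 8)
    return Volume3D(rng.normal(size=shape), centered_affine(shape))


@pytest.fixture(scope="session")
def fixture_phantom_pet():
    """Miniature phantom, PET modality only (fast)."""
    return generate_phantom(PhantomSpec.fixture(rng_seed=11), modalities=("pet",))


@pytest.fixture(scope="session")
def fixture_phantom_full():
    """Miniature phantom including DWI."""
    return generate_phantom(PhantomSpec.fixture(rng_seed=11))


@pytest.fixture(scope="session")
def default_phantom_pet():
    """Full-size phantom, PET only, shared across tests that need realistic
    AI statistics."""
    return generate_phantom(PhantomSpec(rng_seed=42), modalities=("pet",))
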