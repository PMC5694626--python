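import numpy as np
import pytest

from eigensynth.io_imaging import VolumeGeometry, VoxelDataset
from eigensynth.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Two-class 16^3 phantom used across the unit tests (fast to build)."""
    spec = PhantomSpec(
        shape=(16, 16, 16),
        class_names=("A", "B"),
        n_per_class=(20, 20),
        class_effects={"A": [], "B": [((8, 8, 8), 2.5, 0.6)]},
        latent_dim=3,
        latent_sd=(0.3, 0.2, 0.1),
        noise_sd=0.1,
        smoothing_fwhm=2.0,
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_dataset(small_phantom):
    return small_phantom[0]


@pytest.fixture()
def tiny_geometry():
    return VolumeGeometry(shape=(4, 4, 4), affine=np.eye(4))


@pytest.fixture()
def tiny_dataset(tiny_geometry):
    """Deterministic 6-subject dataset on a full 4^3 mask."""
    rng = np.random.default_rng(0)
    mask = np.ones((4, 4, 4), dtype=bool)
    data = rng.uniform(0.5, 2.0, size=(6, 64))
    labels = np.array(["x", "x", "x", "y", "y", "y"], dtype=object)
    return VoxelDataset(data=data, labels=labels, mask=mask, geometry=tiny_geometry)
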