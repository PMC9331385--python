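import numpy as np
import pytest

from xpctseg import PhantomSpec, VolumeImage, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """8-slice 64x64 phantom: fast enough for per-test reconstruction."""
    return PhantomSpec(volume_shape=(8, 64, 64), bulb_center_drift=0.0,
                       inclusion_density=(0.0,) * 5, noise_sigma=0.0,
                       fringe_strength=0.0, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture()
def disk_image() -> np.ndarray:
    """Uniform disk of density 0.8, radius 20 px, centred in 64x64."""
    yy, xx = np.mgrid[0:64, 0:64] - 31.5
    return np.where(yy ** 2 + xx ** 2 <= 20.0 ** 2, 0.8, 0.0).astype(np.float32)


@pytest.fixture()
def disk_volume(disk_image) -> VolumeImage:
    return VolumeImage(disk_image[None], pixel_size=1.0)
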