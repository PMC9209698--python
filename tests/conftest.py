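import numpy as np
import pytest

from fetalgan import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_phantom_config():
    """A 24-voxel grid phantom: big enough for 16-voxel patches, fast to build."""
    return PhantomConfig(
        grid_shape=(24, 24, 24),
        brain_semiaxes_range=(6.0, 8.0),
        contrast=1.5,
        noise_sigma=0.02,
        bias_amplitude=0.1,
        n_surround_blobs=3,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_config):
    return generate_phantom(small_phantom_config, seed=42)
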