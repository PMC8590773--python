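import numpy as np
import pytest

from lymphseg import BinaryMask3D, PhantomSpec, Volume3D, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, tube-free phantom with 3 nodes (session-cached)."""
    spec = PhantomSpec(n_nodes=3, n_tubes=0, noise_sd=0.0, seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-condition phantom (nodes + tubes + noise)."""
    return generate_phantom(PhantomSpec(seed=21))


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask3D(np.asarray(data, dtype=np.uint8), spacing)


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return Volume3D(np.asarray(data, dtype=np.float32), spacing)
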