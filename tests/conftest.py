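import numpy as np
import pytest

from voxcodec import fixture_suite


@pytest.fixture(scope="session")
def suite() -> dict[str, np.ndarray]:
    """The deterministic synthetic volume suite (default seed)."""
    return fixture_suite()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_sparse_volume(rng: np.random.Generator, max_side: int = 32) -> np.ndarray:
    """A random volume with a sparse nonzero support (at least one voxel)."""
    shape = tuple(int(s) for s in rng.integers(1, max_side + 1, size=3))
    vol = np.zeros(shape, dtype=np.uint8)
    n = int(rng.integers(1, max(2, vol.size // 8)))
    idx = rng.integers(0, vol.size, size=n)
    vol.ravel()[idx] = rng.integers(1, 256, size=n)
    return vol
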