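import numpy as np
import pytest

from dmta.preprocess import RoughnessSurface
from dmta.synthetic_data import gaussian_random_field


def as_rough(z: np.ndarray, dx: float = 0.44, dy: float = 0.44
             ) -> RoughnessSurface:
    """Wrap an array as a mean-zero roughness surface."""
    z = np.asarray(z, dtype=float)
    return RoughnessSurface(z - z.mean(), dx, dy)


@pytest.fixture
def rng():
    return np.random.default_rng(20210128)


@pytest.fixture
def small_grf():
    """Factory for small Gaussian-random-field roughness surfaces."""

    def make(n: int = 16, seed: int = 0, sq: float = 0.5,
             corr_len: float = 1.5, dx: float = 0.44) -> RoughnessSurface:
        m = gaussian_random_field(n, n, dx, dx, sq=sq, corr_len=corr_len,
                                  seed=seed)
        return as_rough(m.heights, dx, dx)

    return make
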