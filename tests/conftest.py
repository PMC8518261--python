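import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_pd(p: int, rng: np.random.Generator, cond_boost: float = 0.1) -> np.ndarray:
    """A random symmetric positive-definite matrix with bounded conditioning."""
    A = rng.standard_normal((p, p))
    return A @ A.T / p + cond_boost * np.eye(p)


@pytest.fixture
def small_pd(rng):
    return random_pd(5, rng)
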