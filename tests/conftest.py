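import numpy as np
import pytest

from fsinet.synthetic import SyntheticSpec, default_catalog, generate


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale synthetic bundle with informative planted structure."""
    return generate(SyntheticSpec(n_drugs=40, n_targets=50, seed=11))


@pytest.fixture(scope="session")
def small_catalog(small_bundle):
    """Full measure catalog for the small bundle, without the two
    alignment measures (kept out of the hot path for speed)."""
    return default_catalog(small_bundle, include_alignment=False)


def random_similarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix in [0, 1] with unit diagonal."""
    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a
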