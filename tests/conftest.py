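import numpy as np
import pytest

import extdebt as ed


@pytest.fixture(scope="session")
def small_world():
    """A small heterogeneous synthetic world shared by read-only tests."""
    return ed.generate_world(ed.SyntheticConfig(seed=5, resolution=8.0))


@pytest.fixture(scope="session")
def small_world_richness(small_world):
    kept = ed.filter_forest_terrestrial(small_world.species)
    return ed.rasterize_richness(kept, small_world.grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def exact_correlated_triple(n=120, r_xy=0.5, r_xz=0.5, r_yz=0.5, seed=0):
    """Three variables whose *sample* correlation matrix is exactly the
    target: orthonormal centered basis times a Cholesky factor."""
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n, 4))
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), raw]))
    basis = q[:, 1:4] * np.sqrt(n)  # centered, orthonormal columns scaled
    target = np.array([
        [1.0, r_xy, r_xz],
        [r_xy, 1.0, r_yz],
        [r_xz, r_yz, 1.0],
    ])
    chol = np.linalg.cholesky(target)
    v = basis @ chol.T
    return v[:, 0], v[:, 1], v[:, 2]


def centered_orthogonal_design(n, p, seed=0):
    """Columns that are exactly mutually orthogonal after centering."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), rng.standard_normal((n, p))]))
    return q[:, 1:p + 1]
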