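import numpy as np
import pytest

import lungheq as lh


@pytest.fixture
def rng():
    return np.random.default_rng(20190122)


@pytest.fixture(scope="session")
def default_cohort():
    """One study-scale synthetic cohort shared by read-only tests."""
    df, truth = lh.generate_cohort(lh.CohortSpec(seed=7))
    return df, truth


@pytest.fixture(scope="session")
def small_phantom():
    spec = lh.PhantomSpec(n_components=4, n_enclosed=2, seed=5)
    return lh.generate_phantom(spec)


def random_binary_slice(rng, shape):
    """A BinarySlice over a random {0,1} grid (threshold metadata is nominal)."""
    grid = (rng.random(shape) < rng.uniform(0.2, 0.8)).astype(int)
    return lh.BinarySlice(
        values=grid,
        threshold_hu=-880.0,
        n_lung_pixels=grid.size,
        n_low_pixels=int((grid == 0).sum()),
    )
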