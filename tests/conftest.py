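import numpy as np
import pytest

from ptcrad.phantoms import PhantomConfig, generate_cohort


def toy_grid_441():
    """The 4x4x1 hand-enumerable gray-level grid."""
    levels = np.array(
        [[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]], dtype=np.int32
    )[:, :, None]
    return levels


@pytest.fixture(scope="session")
def toy_grids():
    """Small fully-masked discretized grids for oracle comparisons."""
    rng = np.random.default_rng(42)
    grids = [toy_grid_441()]
    grids.append(np.ones((3, 3, 3), dtype=np.int32))  # single level
    grids.append(rng.integers(1, 5, size=(5, 4, 3)).astype(np.int32))
    grids.append(rng.integers(1, 7, size=(6, 6, 2)).astype(np.int32))
    # grid with a masked-out hole (level 0)
    g = rng.integers(1, 4, size=(4, 4, 4)).astype(np.int32)
    g[1:3, 1:3, 1:3] = 0
    grids.append(g)
    return grids


@pytest.fixture(scope="session")
def small_cohort():
    """Four phantom cases (two per class) on a small grid."""
    config = PhantomConfig(n_cases_per_class=2, grid_shape=(32, 32, 32), seed=11)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def one_case(small_cohort):
    return small_cohort[0]
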