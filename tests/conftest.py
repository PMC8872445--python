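import numpy as np
import pytest

from luces.grid import CLASS_CODES, LandCoverGrid
from luces.synthetic import SyntheticConfig, make_initial_lucc, make_terrain


@pytest.fixture(scope="session")
def terrain_small():
    """Deterministic 60×60 synthetic terrain stack."""
    return make_terrain(SyntheticConfig(shape=(60, 60), seed=7))


@pytest.fixture(scope="session")
def lucc_small(terrain_small):
    """Deterministic 60×60 land-cover map on the synthetic terrain."""
    return make_initial_lucc(terrain_small, seed=7)


def random_landcover(seed: int, shape=(20, 20), cell_size: float = 30.0) -> LandCoverGrid:
    rng = np.random.default_rng(seed)
    values = rng.integers(1, len(CLASS_CODES) + 1, size=shape)
    return LandCoverGrid(values, cell_size=cell_size)
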