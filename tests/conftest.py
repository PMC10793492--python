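import numpy as np
import pandas as pd
import pytest

from tilarch.features import CellMap


def random_cellmap(rng, n_max: int = 200, tile_size: float = 400.0,
                   clustered: bool = True, tile_id: str = "t",
                   compartment: str = "epithelium") -> CellMap:
    """A random mixed-family tile, optionally with clumped TILs."""
    n_til = int(rng.integers(0, n_max // 2 + 1))
    n_non = int(rng.integers(0, n_max - n_til + 1))
    if clustered and n_til:
        centers = rng.uniform(0, tile_size, size=(max(1, n_til // 12), 2))
        pick = rng.integers(0, len(centers), size=n_til)
        xy_til = centers[pick] + rng.normal(0, tile_size / 20, size=(n_til, 2))
        xy_til = np.clip(xy_til, 0, np.nextafter(tile_size, 0))
    else:
        xy_til = rng.uniform(0, tile_size, size=(n_til, 2))
    xy_non = rng.uniform(0, tile_size, size=(n_non, 2))
    return CellMap.from_arrays(tile_id, compartment, tile_size, xy_til, xy_non)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_cellmap():
    """Small fixed tile: one tight TIL triangle + two far non-TILs."""
    cells = pd.DataFrame({
        "x_um": [0.0, 4.0, 0.0, 200.0, 350.0],
        "y_um": [0.0, 0.0, 3.0, 200.0, 350.0],
        "family": ["TIL", "TIL", "TIL", "nonTIL", "nonTIL"],
    })
    return CellMap("fixed", "epithelium", 400.0, cells)
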