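import numpy as np
import pandas as pd
import pytest

from pescore.features import assemble_feature_table, compute_range_cells
from pescore.grid import WORLD_GRID
from pescore.partition import binarize_category
from pescore.world import generate_world


@pytest.fixture(scope="session")
def grid():
    return WORLD_GRID


@pytest.fixture(scope="session")
def small_world():
    """A compact world shared by tests that only need realistic structure."""
    return generate_world(seed=11, n_species=250)


@pytest.fixture(scope="session")
def small_table(small_world):
    w = small_world
    cells = compute_range_cells(w.species, w.grid)
    table = assemble_feature_table(w.species, w.occurrences, w.layers, w.grid, cells)
    table["label"] = table["category"].map(binarize_category)
    return table


@pytest.fixture(scope="session")
def small_range_cells(small_world):
    return compute_range_cells(small_world.species, small_world.grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def planted_table(n: int, n_causal: int, n_noise: int, seed: int,
                  betas=(1.5, -1.2, 1.0), intercept=-1.1) -> tuple[pd.DataFrame, np.ndarray]:
    """Plain logistic-label table: causal columns f00.., noise columns g00.."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((n, n_causal + n_noise)),
        columns=[f"f{i:02d}" for i in range(n_causal)] + [f"g{i:02d}" for i in range(n_noise)],
    )
    eta = intercept + sum(b * X.iloc[:, i] for i, b in enumerate(betas[:n_causal]))
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y
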