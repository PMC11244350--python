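import numpy as np
import pytest

import niche_shift as ns
from niche_shift.geo import LatLonGrid, RasterLayer, RasterStack


@pytest.fixture(scope="session")
def small_world():
    """A 60x60 virtual world shared by the slower model tests."""
    cfg = ns.default_config(seed=11, n_rows=60, n_cols=60, n_presence=150)
    stack, truth = ns.generate_stack(cfg)
    occ = ns.sample_presences(stack, truth, cfg.n_presence, seed=12)
    return cfg, stack, truth, occ


@pytest.fixture(scope="session")
def fitted_small(small_world):
    """A fitted model on the small world (session-scoped: fits are the slow part)."""
    cfg, stack, truth, occ = small_world
    train, test = ns.split(occ, ns.SplitConfig(seed=13))
    model = ns.MaxEnt.from_occurrences(train, stack, background_size=1500, seed=14)
    res = model.fit()
    return stack, truth, train, test, res


def make_layer(values, west=100.0, south=20.0, cell=1.0, name="layer"):
    values = np.asarray(values, dtype=float)
    grid = LatLonGrid(n_rows=values.shape[0], n_cols=values.shape[1],
                      west_deg=west, south_deg=south, cell_deg=cell)
    return RasterLayer(grid=grid, name=name, values=values)


@pytest.fixture
def toy_stack():
    """3x3 stack whose single layer encodes row*10+col, for index arithmetic."""
    vals = np.arange(9, dtype=float).reshape(3, 3)
    vals = (vals // 3) * 10 + vals % 3
    return RasterStack([make_layer(vals, name="code")])
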