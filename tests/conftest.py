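import numpy as np
import pandas as pd
import pytest

from lsmosaic.phantom import CELL_COLUMNS, Appearance, render_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cells(rows):
    """Cell table from (x, y, z, radius) tuples."""
    return pd.DataFrame(
        [(i, x, y, z, r, 1.0, "IV") for i, (x, y, z, r) in enumerate(rows)],
        columns=CELL_COLUMNS,
    )


@pytest.fixture
def single_sphere_volume():
    """One uniform soma of radius 4 µm rendered at 1 µm pitch."""
    cells = make_cells([(25.0, 25.0, 25.0, 4.0)])
    bbox = np.array([[0.0, 50.0]] * 3)
    return render_phantom(cells, bbox, 1.0, Appearance(mode="uniform"))
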