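import numpy as np
import pytest

from palmrisk import Grid, load_rule_registry


@pytest.fixture(scope="session")
def registry():
    return load_rule_registry()


@pytest.fixture
def make_grid():
    """Factory for small test grids with 1 km cells (100 ha each)."""

    def _make(cells, cell_size=1000.0, nodata=None, crs_id="EPSG:32749"):
        cells = np.asarray(cells)
        return Grid(
            cells=cells,
            x_origin=0.0,
            y_origin=cells.shape[0] * cell_size,
            cell_size=cell_size,
            nodata=nodata,
            crs_id=crs_id,
        )

    return _make
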