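import numpy as np
import pandas as pd
import pytest

from cortaxis.io import AxisSpec, CellTable, CountMatrix
from cortaxis.pseudobulk import PseudobulkMatrix

NINE_REGIONS = ("ACC", "DFC", "FI", "M1C", "S1C", "MTG", "A1C", "AnG", "V1C")


@pytest.fixture
def rc_axis() -> AxisSpec:
    return AxisSpec("RC", NINE_REGIONS)


@pytest.fixture
def small_cells() -> CellTable:
    """Six cells: 2 regions x 2 donors (one empty group), two subclasses."""
    return CellTable(
        pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(6)],
                "subclass": ["A", "A", "A", "A", "B", "B"],
                "region": ["ACC", "ACC", "V1C", "V1C", "ACC", "V1C"],
                "donor": ["D1", "D1", "D1", "D2", "D1", "D1"],
            }
        )
    )


@pytest.fixture
def small_counts(small_cells) -> CountMatrix:
    counts = np.array(
        [
            [1, 3, 2, 0, 7, 1],
            [2, 4, 0, 5, 1, 1],
            [0, 0, 1, 1, 0, 9],
        ]
    )
    return CountMatrix(["g1", "g2", "g3"], list(small_cells.cell_ids), counts)


@pytest.fixture
def linear_pseudobulk(rc_axis) -> PseudobulkMatrix:
    """9 one-donor samples; g_up rises linearly with order, g_down falls."""
    order = np.arange(9)
    counts = np.vstack(
        [
            100 + 10 * order,   # increasing
            180 - 10 * order,   # decreasing
            np.full(9, 140),    # flat
        ]
    )
    samples = [(r, "D1") for r in rc_axis.ordered_regions]
    return PseudobulkMatrix(["g_up", "g_down", "g_flat"], samples, counts, "A")
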