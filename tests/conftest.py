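import numpy as np
import pandas as pd
import pytest

import fibroniche as fn

FOCUS = "fibroblastic foci/fibrous tissue"


@pytest.fixture(scope="session")
def focus_section():
    """20×20 hex section with one planted focus disk at the center."""
    pitch = 100.0
    center = (19 * pitch / 2, 19 * pitch * np.sqrt(3) / 4)
    grid, counts, dens, ann, truth = fn.simulate_section(
        n_rows=20, n_cols=20, n_genes=100, k=3, seed=42,
        region_spec=[(FOCUS, center, 300.0)],
    )
    return grid, counts, dens, ann, truth


@pytest.fixture(scope="session")
def line_grid():
    """Seven collinear spots at 100 µm pitch; leftmost is the ROI."""
    ids = [f"s{i}" for i in range(7)]
    grid = pd.DataFrame(
        {
            "sample_id": "line",
            "x_um": np.arange(7) * 100.0,
            "y_um": 0.0,
            "array_row": 0,
            "array_col": np.arange(7),
            "in_tissue": True,
        },
        index=pd.Index(ids, name="spot_id"),
    )
    return grid, {"s0"}


def brute_force_field(grid, roi, pitch):
    """O(N·|ROI|) oracle for the signed radial distance."""
    xy = grid[["x_um", "y_um"]].to_numpy(float)
    idx = list(grid.index)
    roi_pos = [i for i, s in enumerate(idx) if s in roi]
    ext_pos = [i for i, s in enumerate(idx) if s not in roi]
    d = {}
    for i, s in enumerate(idx):
        if s in roi:
            dist = min(np.hypot(*(xy[i] - xy[j])) for j in ext_pos)
            d[s] = -dist
        else:
            dist = min(np.hypot(*(xy[i] - xy[j])) for j in roi_pos)
            d[s] = max(0.0, dist - pitch)
    return pd.Series(d)
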