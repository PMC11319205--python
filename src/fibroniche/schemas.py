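"""In-memory containers and their validators.

All pipeline stages exchange plain pandas objects with fixed schemas rather
than bespoke classes, in the statsmodels/scanpy tradition of DataFrame-first
APIs:

* **SpotGrid** — ``DataFrame`` indexed by ``spot_id`` (the barcode) with
  columns ``sample_id`` (str), ``x_um``/``y_um`` (planar coordinates in µm,
  image convention: y grows downward), ``array_row``/``array_col`` (int
  lattice indices) and ``in_tissue`` (bool).
* **CountMatrix** — spots × genes ``DataFrame`` of non-negative integer UMI
  counts; index is a subset of a SpotGrid's spot_ids.
* **NormalizedMatrix** — spots × genes ``DataFrame`` of non-negative floats
  (log1p CP10K).
* **RegionAnnotation** — ``Series`` mapping spot_id → histology label.
* **CellDensityMatrix** — spots × cell-types ``DataFrame`` of non-negative
  inferred densities (external deconvolution output).
* **RadialDistanceField** — ``DataFrame`` indexed by spot_id with columns
  ``d_um`` (signed distance, ≤0 inside the region of interest), ``is_roi``
  (bool) and ``sample_id``.

Validators raise ``ValueError`` with a message naming the violated
invariant; they return the (possibly coerced) object so they compose.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

SPOT_GRID_COLUMNS = ("sample_id", "x_um", "y_um", "array_row", "array_col", "in_tissue")


def validate_spot_grid(grid: pd.DataFrame, pitch_um: float | None = None) -> pd.DataFrame:
    """Check SpotGrid invariants; returns the grid.

    When ``pitch_um`` is given, also enforces that the minimum pairwise
    center distance within each sample is at least 0.9 × pitch.
    """
    missing = [c for c in SPOT_GRID_COLUMNS if c not in grid.columns]
    if missing:
        raise ValueError(f"SpotGrid missing columns: {missing}")
    dup = grid.groupby("sample_id", observed=True).apply(
        lambda g: g.index.duplicated().any(), include_groups=False
    )
    if bool(dup.any()):
        raise ValueError("SpotGrid: duplicate spot_id within a sample")
    if not grid["in_tissue"].astype(bool).all():
        raise ValueError("SpotGrid: retained spots must all have in_tissue=True")
    if pitch_um is not None:
        for sid, sub in grid.groupby("sample_id", observed=True):
            if len(sub) < 2:
                continue
            xy = sub[["x_um", "y_um"]].to_numpy(float)
            d, _ = cKDTree(xy).query(xy, k=2)
            if d[:, 1].min() < 0.9 * pitch_um:
                raise ValueError(
                    f"SpotGrid: sample {sid!r} has spot centers closer than 0.9×pitch"
                )
    return grid


def validate_counts(counts: pd.DataFrame, grid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check CountMatrix invariants (non-negative integers, unique gene ids)."""
    if counts.columns.duplicated().any():
        raise ValueError("CountMatrix: duplicate gene ids")
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("CountMatrix: negative entries")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("CountMatrix: non-integer entries")
    if grid is not None and not counts.index.isin(grid.index).all():
        raise ValueError("CountMatrix: spot ids not present in the grid")
    return counts


def validate_annotation(
    annotation: pd.Series,
    grid: pd.DataFrame | None = None,
    vocabulary: set[str] | None = None,
) -> pd.Series:
    """Check RegionAnnotation invariants."""
    if annotation.index.duplicated().any():
        raise ValueError("RegionAnnotation: duplicate spot ids")
    if grid is not None and not annotation.index.isin(grid.index).all():
        raise ValueError("RegionAnnotation: labeled spot absent from the grid")
    if vocabulary is not None:
        bad = set(annotation.unique()) - set(vocabulary)
        if bad:
            raise ValueError(f"RegionAnnotation: labels outside vocabulary: {sorted(bad)}")
    return annotation


def validate_densities(densities: pd.DataFrame) -> pd.DataFrame:
    """Check CellDensityMatrix invariants (non-negative, no all-missing column)."""
    if densities.columns.duplicated().any():
        raise ValueError("CellDensityMatrix: duplicate cell-type columns")
    if densities.isna().all(axis=0).any():
        raise ValueError("CellDensityMatrix: all-missing column")
    if (densities.to_numpy(float) < -0.0).any():
        if (densities.to_numpy(float) < 0).any():
            raise ValueError("CellDensityMatrix: negative density")
    return densities


def infer_pitch(grid: pd.DataFrame) -> float:
    """Lattice pitch in µm, estimated as the median nearest-neighbor
    center distance across samples."""
    nn = []
    for _, sub in grid.groupby("sample_id", observed=True):
        if len(sub) < 2:
            continue
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        d, _ = cKDTree(xy).query(xy, k=2)
        nn.append(d[:, 1])
    if not nn:
        raise ValueError("cannot infer pitch from a grid with <2 spots per sample")
    return float(np.median(np.concatenate(nn)))
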