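"""Readers and writers for the spatial file formats the pipeline touches.

Input side: Space Ranger-style ``filtered_feature_bc_matrix`` directories
(Matrix Market triplet + barcode and feature lists), tissue-positions tables
in both the legacy headerless 6-column dialect and the headered dialect,
and generic per-spot annotation/density tables. Output side: TSV and JSON
with enough float precision that a write/read round trip reproduces tables
to 1e-9.

All downstream modules consume only the pandas containers documented in
:mod:`fibroniche.schemas`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .schemas import validate_annotation, validate_counts, validate_densities

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"  # enough digits for exact float64 round trips

_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required file not found: {path}")
    return path


def _find_matrix_files(matrix_dir: Path) -> tuple[Path, Path, Path]:
    matrix_dir = Path(matrix_dir)
    if not matrix_dir.is_dir():
        raise FileNotFoundError(f"matrix directory not found: {matrix_dir}")

    def pick(names: list[str], what: str) -> Path:
        for n in names:
            p = matrix_dir / n
            if p.exists():
                return p
        raise FileNotFoundError(f"no {what} file in {matrix_dir} (looked for {names})")

    mtx = pick(["matrix.mtx", "matrix.mtx.gz"], "Matrix Market")
    barcodes = pick(["barcodes.tsv", "barcodes.tsv.gz"], "barcode list")
    features = pick(["features.tsv", "features.tsv.gz", "genes.tsv"], "feature list")
    return mtx, barcodes, features


def read_positions(positions_path: Path, um_per_pixel: float) -> pd.DataFrame:
    """Parse a tissue-positions table (either dialect) into a SpotGrid.

    Pixel coordinates are converted to µm with the supplied per-sample
    scale factor; ``x_um`` comes from the full-resolution column (image x),
    ``y_um`` from the row (image y, growing downward).
    """
    positions_path = _require(Path(positions_path))
    with open(positions_path) as fh:
        first = fh.readline()
    headered = "barcode" in first.lower()
    if headered:
        pos = pd.read_csv(positions_path)
        rename = {c: c.strip().lower() for c in pos.columns}
        pos = pos.rename(columns=rename)
    else:
        pos = pd.read_csv(positions_path, header=None, names=_POSITION_COLUMNS)
    missing = [c for c in _POSITION_COLUMNS if c not in pos.columns]
    if missing:
        raise ValueError(f"positions table {positions_path} missing columns {missing}")
    grid = pd.DataFrame(
        {
            "sample_id": "",
            "x_um": pos["pxl_col_in_fullres"].to_numpy(float) * um_per_pixel,
            "y_um": pos["pxl_row_in_fullres"].to_numpy(float) * um_per_pixel,
            "array_row": pos["array_row"].to_numpy(int),
            "array_col": pos["array_col"].to_numpy(int),
            "in_tissue": pos["in_tissue"].to_numpy(int).astype(bool),
        },
        index=pd.Index(pos["barcode"].astype(str).to_numpy(), name="spot_id"),
    )
    if grid.index.duplicated().any():
        raise ValueError(f"positions table {positions_path}: duplicate barcodes")
    return grid


def read_visium_bundle(
    matrix_dir: Path,
    positions_path: Path,
    sample_id: str,
    um_per_pixel: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a Space Ranger-like bundle into (CountMatrix, SpotGrid).

    Counts are restricted to in-tissue barcodes present in both the matrix
    and the positions table. Gene identity for the count columns is the
    feature id when available, else the symbol; collisions are resolved by
    suffixing and logged.
    """
    mtx_path, bc_path, ft_path = _find_matrix_files(Path(matrix_dir))
    mat = spio.mmread(mtx_path)  # features x barcodes, Space Ranger layout
    mat = sparse.csr_matrix(mat)
    if mat.nnz and mat.data.min() < 0:
        raise ValueError(f"negative counts in {mtx_path}")

    barcodes = pd.read_csv(bc_path, header=None, sep="\t")[0].astype(str).tolist()
    features = pd.read_csv(ft_path, header=None, sep="\t")
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match features×barcodes "
            f"({len(features)}×{len(barcodes)})"
        )
    gene_ids = features[0].astype(str)
    if gene_ids.duplicated().any() and features.shape[1] > 1:
        gene_ids = features[1].astype(str)
    if gene_ids.duplicated().any():
        log.warning("duplicate gene identifiers; suffixing duplicates")
        counts_by_id = gene_ids.groupby(gene_ids).cumcount()
        gene_ids = gene_ids.where(counts_by_id == 0, gene_ids + "." + counts_by_id.astype(str))

    grid = read_positions(positions_path, um_per_pixel)
    grid["sample_id"] = sample_id

    shared = [b for b in barcodes if b in grid.index]
    if not shared:
        raise ValueError("barcode sets of matrix and positions table are disjoint")
    keep = [b for b in shared if bool(grid.loc[b, "in_tissue"])]
    col_idx = [barcodes.index(b) for b in keep]
    dense = np.asarray(mat[:, col_idx].todense()).T  # spots x genes
    counts = pd.DataFrame(dense.astype(np.int64), index=pd.Index(keep, name="spot_id"),
                          columns=pd.Index(gene_ids.tolist(), name="gene_id"))
    grid = grid.loc[keep]
    return validate_counts(counts, grid), grid


def read_spot_table(path: Path, kind: str) -> pd.Series | pd.DataFrame:
    """Read an annotation (``kind='annotation'``) or density
    (``kind='density'``) table keyed by barcode.

    The barcode column is the first column (or one named barcode/spot_id).
    Density tables must be numeric and non-negative in the remaining
    columns; an unparseable cell raises with its row/column location.
    """
    path = _require(Path(path))
    if kind not in {"annotation", "density"}:
        raise ValueError(f"unknown kind {kind!r}")
    table = pd.read_csv(path, sep=None, engine="python")
    key = next((c for c in table.columns if c.lower() in {"barcode", "spot_id"}),
               table.columns[0])
    table = table.set_index(table[key].astype(str)).drop(columns=[key])
    table.index.name = "spot_id"
    if table.index.duplicated().any():
        raise ValueError(f"{path}: duplicate barcodes")
    if kind == "annotation":
        if table.shape[1] < 1:
            raise ValueError(f"{path}: annotation table needs a label column")
        return validate_annotation(table.iloc[:, 0].astype(str).rename("label"))
    out = {}
    for col in table.columns:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() & table[col].notna()
        if bad.any():
            row = table.index[bad.to_numpy()][0]
            raise ValueError(f"{path}: unparseable numeric cell at row {row!r}, column {col!r}")
        if (vals < 0).any():
            raise ValueError(f"{path}: negative density in column {col!r}")
        out[col] = vals
    return validate_densities(pd.DataFrame(out, index=table.index))


def write_results(result, path: Path, format: str = "tsv") -> Path:
    """Write a pipeline output (DataFrame/Series or JSON-able mapping).

    TSV uses 17 significant digits so the round trip through
    :func:`read_results` is exact to float precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        if isinstance(result, pd.Series):
            result = result.to_frame()
        if not isinstance(result, pd.DataFrame):
            raise ValueError("tsv format requires a DataFrame/Series result")
        result.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    elif format == "json":
        if isinstance(result, (pd.DataFrame, pd.Series)):
            payload = json.loads(result.to_json(orient="split", double_precision=15))
        else:
            payload = result
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def read_results(path: Path, format: str = "tsv", index_col: int = 0):
    """Inverse of :func:`write_results` for tabular outputs."""
    path = _require(Path(path))
    if format == "tsv":
        return pd.read_csv(path, sep="\t", index_col=index_col)
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    raise ValueError(f"unknown format {format!r}")


def write_bundle(
    grid: pd.DataFrame,
    counts: pd.DataFrame,
    out_dir: Path,
    um_per_pixel: float = 1.0,
) -> Path:
    """Write a (grid, counts) pair as a Space Ranger-like bundle so that a
    simulated section is a drop-in for :func:`read_visium_bundle`."""
    out_dir = Path(out_dir)
    mdir = out_dir / "filtered_feature_bc_matrix"
    mdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(counts.to_numpy().T)  # features x barcodes
    spio.mmwrite(mdir / "matrix.mtx", mat.tocoo(), field="integer")
    pd.Series(counts.index).to_csv(mdir / "barcodes.tsv", index=False, header=False)
    feats = pd.DataFrame({0: counts.columns, 1: counts.columns, 2: "Gene Expression"})
    feats.to_csv(mdir / "features.tsv", sep="\t", index=False, header=False)
    pos = pd.DataFrame(
        {
            "barcode": grid.index,
            "in_tissue": grid["in_tissue"].astype(int).to_numpy(),
            "array_row": grid["array_row"].to_numpy(),
            "array_col": grid["array_col"].to_numpy(),
            "pxl_row_in_fullres": grid["y_um"].to_numpy() / um_per_pixel,
            "pxl_col_in_fullres": grid["x_um"].to_numpy() / um_per_pixel,
        }
    )
    pos.to_csv(out_dir / "tissue_positions.csv", index=False, float_format=_FLOAT_FMT)
    return out_dir
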