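"""Hex-lattice geometry: adjacency graphs, connected components, signed
radial-distance fields around annotated regions, and distance binning.

The distance convention follows the field's radial-distance tooling for
spot lattices: for a spot outside the region of interest (ROI),
``d = max(0, euclidean distance to the nearest ROI spot center − pitch)``,
so the first exterior ring sits at exactly 0 µm and each further ring adds
one pitch (100 µm bins correspond to one row of spots). ROI spots get
``d = −(distance to the nearest exterior spot center)``, i.e. strictly
negative. A hop-count alternative (``d = (hops − 1) × pitch``) is provided
for sensitivity checks.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .schemas import infer_pitch


def build_adjacency(grid: pd.DataFrame, adjacency_radius_um: float | None = None) -> nx.Graph:
    """Undirected spot graph: edge iff center distance ≤ radius, within a
    sample (no cross-sample edges). Default radius is 1.2 × inferred pitch,
    which links each interior hex spot to its 6 neighbors."""
    if grid.empty:
        raise ValueError("grid is empty")
    if adjacency_radius_um is None:
        adjacency_radius_um = 1.2 * infer_pitch(grid)
    if adjacency_radius_um <= 0:
        raise ValueError("adjacency radius must be > 0")
    g = nx.Graph()
    for sid, sub in grid.groupby("sample_id", observed=True):
        ids = sub.index.to_numpy()
        g.add_nodes_from(ids, sample_id=sid)
        if len(sub) < 2:
            continue
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        tree = cKDTree(xy)
        nn = tree.query(xy, k=2)[0][:, 1].min()
        if adjacency_radius_um < nn:
            warnings.warn(
                f"adjacency radius {adjacency_radius_um:g} µm below the lattice "
                f"pitch of sample {sid!r}; graph will be edgeless"
            )
        for i, j in tree.query_pairs(adjacency_radius_um):
            g.add_edge(ids[i], ids[j])
    return g


def connected_components(graph: nx.Graph, subset) -> list[set]:
    """Partition ``subset`` by adjacency restricted to the subset.

    Components are sorted by size (descending), ties by smallest spot id;
    size-1 components are the singletons downstream callers may drop.
    """
    subset = set(subset)
    unknown = subset - set(graph.nodes)
    if unknown:
        raise ValueError(f"unknown spots in subset: {sorted(unknown)[:5]}")
    comps = [set(c) for c in nx.connected_components(graph.subgraph(subset))]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def radial_distance_field(
    grid: pd.DataFrame,
    roi,
    graph: nx.Graph | None = None,
    include_singletons: bool = True,
    pitch_um: float | None = None,
    mode: str = "euclidean",
) -> pd.DataFrame:
    """Signed per-spot distance (µm) to an ROI spot set, per sample.

    Returns a DataFrame indexed by spot_id with columns ``d_um``,
    ``is_roi`` and ``sample_id``. Samples without ROI spots get NaN
    distances. ``include_singletons=False`` drops size-1 ROI components
    (under lattice adjacency) from the anchor set first.

    ``mode='euclidean'`` (default): exterior ``d = max(0, dist − pitch)``,
    ROI ``d = −dist to nearest exterior center``. ``mode='hops'``:
    exterior ``d = (graph hops − 1) × pitch``, ROI ``d = −hops × pitch``
    to the nearest exterior spot.
    """
    roi = set(roi)
    unknown = roi - set(grid.index)
    if unknown:
        raise ValueError(f"ROI spots not in grid: {sorted(unknown)[:5]}")
    if pitch_um is None:
        pitch_um = infer_pitch(grid)
    if not include_singletons:
        if graph is None:
            graph = build_adjacency(grid)
        comps = connected_components(graph, roi)
        roi = set().union(*(c for c in comps if len(c) > 1)) if comps else set()
    if not roi:
        raise ValueError("ROI is empty (or emptied by singleton removal)")
    if mode not in {"euclidean", "hops"}:
        raise ValueError("mode must be 'euclidean' or 'hops'")
    if mode == "hops" and graph is None:
        graph = build_adjacency(grid)

    d = pd.Series(np.nan, index=grid.index, dtype=float)
    is_roi = pd.Series(False, index=grid.index)
    is_roi.loc[list(roi)] = True
    for sid, sub in grid.groupby("sample_id", observed=True):
        roi_ids = [s for s in sub.index if s in roi]
        ext_ids = [s for s in sub.index if s not in roi]
        if not roi_ids:
            continue
        if mode == "euclidean":
            roi_xy = sub.loc[roi_ids, ["x_um", "y_um"]].to_numpy(float)
            roi_tree = cKDTree(roi_xy)
            if ext_ids:
                ext_xy = sub.loc[ext_ids, ["x_um", "y_um"]].to_numpy(float)
                dist_ext = roi_tree.query(ext_xy)[0]
                d.loc[ext_ids] = np.maximum(0.0, dist_ext - pitch_um)
                dist_roi = cKDTree(ext_xy).query(roi_xy)[0]
                d.loc[roi_ids] = -dist_roi
            else:
                warnings.warn(f"sample {sid!r}: every spot is in the ROI")
                d.loc[roi_ids] = -pitch_um
        else:
            sg = graph.subgraph(sub.index)
            hops_from_roi = nx.multi_source_dijkstra_path_length(sg, roi_ids, weight=None)
            for s in ext_ids:
                if s in hops_from_roi:
                    d.loc[s] = (hops_from_roi[s] - 1) * pitch_um
            if ext_ids:
                hops_from_ext = nx.multi_source_dijkstra_path_length(sg, ext_ids, weight=None)
                for s in roi_ids:
                    if s in hops_from_ext:
                        d.loc[s] = -hops_from_ext[s] * pitch_um
            else:
                d.loc[roi_ids] = -pitch_um
    return pd.DataFrame({"d_um": d, "is_roi": is_roi, "sample_id": grid["sample_id"]})


def assign_distance_bins(
    field: pd.DataFrame,
    bin_width_um: float = 100.0,
    max_distance_um: float = 3000.0,
    inside_bin: int = -1,
) -> pd.Series:
    """Exterior spots with ``d ∈ [i·w, (i+1)·w)`` map to bin ``i``;
    ``d == max_distance`` is retained, ``d > max_distance`` dropped; ROI
    spots get the reserved inside bin (default −1). Spots with undefined
    distance (ROI-less samples) are dropped."""
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    d = field["d_um"]
    is_roi = field["is_roi"].astype(bool)
    keep = d.notna() & (is_roi | (d <= max_distance_um))
    bins = pd.Series(inside_bin, index=field.index[keep], dtype=int, name="bin")
    ext = keep & ~is_roi
    bins.loc[field.index[ext]] = np.floor(d[ext] / bin_width_um).astype(int)
    return bins
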