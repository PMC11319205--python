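"""Permutation-null spatial enrichment around annotated regions, region
neighborhoods, and feature-vs-distance correlation.

The enrichment statistic: spots are binned by radial distance d from the
region of interest; for each cluster label the observed spot count x_d is
registered per bin; a null is built by shuffling the full per-sample label
multiset (labeled and unlabeled states alike) uniformly k times (default
100) and re-registering counts each round; and

    Z_d = (x_d − μ_d) / σ_d

with μ_d, σ_d the per-bin mean and standard deviation (denominator k−1)
across rounds. Two-sided p-values come from the standard normal by default
or a Student t with k−1 degrees of freedom. Bins beyond the maximum
distance (default 3,000 µm) are discarded before scoring; σ_d = 0 rows are
flagged rather than scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentParams:
    k: int = 100  # number of shuffle rounds
    bin_width_um: float = 100.0
    max_distance_um: float = 3000.0
    seed: int = 0
    p_model: str = "normal"  # or "t" (df = k - 1)

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.bin_width_um <= 0 or self.max_distance_um <= 0:
            raise ValueError("bin width and max distance must be positive")
        if self.p_model not in {"normal", "t"}:
            raise ValueError("p_model must be 'normal' or 't'")


def _p_from_z(z: np.ndarray, params: EnrichmentParams) -> np.ndarray:
    if params.p_model == "normal":
        return 2.0 * stats.norm.sf(np.abs(z))
    return 2.0 * stats.t.sf(np.abs(z), df=params.k - 1)


def border_enrichment_test(
    bins: pd.Series,
    labels: pd.Series,
    sample_ids: pd.Series,
    params: EnrichmentParams = EnrichmentParams(),
    pool_samples: bool = True,
    return_null: bool = False,
) -> pd.DataFrame:
    """Permutation-null Z-score of labeled-spot counts per distance bin.

    ``bins`` maps spots to bin indices (the reserved inside bin included);
    ``labels`` maps spots to a cluster label or NA — its full per-sample
    multiset is what gets shuffled, so spots without a bin still take part
    in the null. With ``pool_samples`` (default) counts are summed across
    samples round-by-round so μ_d/σ_d describe the pooled null; otherwise
    one table per sample is returned concatenated with a ``sample`` column.
    ``return_null`` additionally returns the per-round pooled null counts
    (clusters × bins × rounds) for diagnostics.
    """
    spots = labels.index
    missing = bins.index.difference(spots)
    if len(missing):
        raise ValueError("bins contain spots absent from labels")
    samples = sample_ids.reindex(spots)
    clusters = sorted(labels.dropna().unique())
    if not clusters:
        raise ValueError("no labeled spots")
    bin_levels = np.sort(bins.unique())
    bin_pos = {b: i for i, b in enumerate(bin_levels)}
    rng = np.random.default_rng(params.seed)

    def observed_counts(lab: pd.Series) -> np.ndarray:
        out = np.zeros((len(clusters), len(bin_levels)), dtype=float)
        joined = pd.DataFrame({"bin": bins, "lab": lab.reindex(bins.index)}).dropna()
        for ci, c in enumerate(clusters):
            sub = joined[joined["lab"] == c]
            for b, cnt in sub["bin"].value_counts().items():
                out[ci, bin_pos[b]] += cnt
        return out

    x = observed_counts(labels)
    null = np.zeros((params.k, len(clusters), len(bin_levels)), dtype=float)
    per_sample_tables = []
    for sid, idx in spots.to_series().groupby(samples, observed=True):
        s_spots = idx.index
        lab_arr = labels.loc[s_spots].to_numpy(object)
        s_bins = bins.reindex(s_spots).dropna()
        pos_of = {s: i for i, s in enumerate(s_spots)}
        binned_pos = np.array([pos_of[s] for s in s_bins.index], dtype=int)
        bin_codes = np.array([bin_pos[b] for b in s_bins], dtype=int)
        s_null = np.zeros_like(null)
        for r in range(params.k):
            perm = rng.permutation(len(s_spots))
            permuted = lab_arr[perm]
            at_bins = permuted[binned_pos]
            for ci, c in enumerate(clusters):
                sel = at_bins == c
                if sel.any():
                    s_null[r, ci, :] += np.bincount(
                        bin_codes[sel], minlength=len(bin_levels)
                    )
        null += s_null
        if not pool_samples:
            s_labels = labels.loc[s_spots]
            tab = _table_from_counts(
                observed_counts(s_labels), s_null, clusters, bin_levels,
                bins.reindex(s_spots).dropna(), params,
            )
            tab.insert(0, "sample", sid)
            per_sample_tables.append(tab)

    if pool_samples:
        table = _table_from_counts(x, null, clusters, bin_levels, bins, params)
    else:
        table = pd.concat(per_sample_tables, ignore_index=True)
    if return_null:
        return table, null
    return table


def _table_from_counts(x, null, clusters, bin_levels, bins, params) -> pd.DataFrame:
    mu = null.mean(axis=0)
    sigma = null.std(axis=0, ddof=1)
    occupancy = bins.value_counts()
    rows = []
    for ci, c in enumerate(clusters):
        for bi, b in enumerate(bin_levels):
            s = float(sigma[ci, bi])
            if s > 0:
                z = (x[ci, bi] - mu[ci, bi]) / s
                p = float(_p_from_z(np.asarray(z), params))
            else:
                z, p = np.nan, np.nan
            rows.append(
                {
                    "cluster": c,
                    "bin": int(b),
                    "x": int(x[ci, bi]),
                    "mu": float(mu[ci, bi]),
                    "sigma": s,
                    "z": float(z) if s > 0 else np.nan,
                    "p": p,
                    "n_spots_in_bin": int(occupancy.get(b, 0)),
                    "sigma_zero": s == 0.0,
                }
            )
    return pd.DataFrame(rows)


def region_neighbors(graph: nx.Graph, roi, max_hops: int = 2) -> set:
    """All spots within ``max_hops`` graph hops of the ROI, excluding the
    ROI spots themselves."""
    roi = set(roi)
    if not roi:
        raise ValueError("ROI is empty")
    unknown = roi - set(graph.nodes)
    if unknown:
        raise ValueError(f"ROI spots not in graph: {sorted(unknown)[:5]}")
    visited = set(roi)
    frontier = set(roi)
    out: set = set()
    for _ in range(max_hops):
        nxt = set()
        for node in frontier:
            nxt.update(graph.neighbors(node))
        nxt -= visited
        out |= nxt
        visited |= nxt
        frontier = nxt
    return out


def correlate_with_distance(
    features: pd.DataFrame,
    field: pd.DataFrame,
    max_distance_um: float = 500.0,
    n_variable: int | None = 1000,
    include_inside: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each feature against radial distance within
    a window around the ROI border, with Benjamini–Hochberg correction.

    The window keeps exterior spots with 0 ≤ d ≤ ``max_distance_um`` (plus
    ROI spots when ``include_inside``). When ``n_variable`` is set, only
    the most variable features within the window are tested. Constant
    features are excluded and reported with a flag.
    """
    d = field["d_um"]
    keep = d.notna() & ~field["is_roi"].astype(bool) & (d >= 0) & (d <= max_distance_um)
    if include_inside:
        keep |= field["is_roi"].astype(bool) & d.notna()
    window = field.index[keep].intersection(features.index)
    if len(window) < 10:
        raise ValueError(f"only {len(window)} spots in the distance window; need >= 10")
    feats = features.loc[window]
    dist = d.loc[window].to_numpy(float)

    variances = feats.var(axis=0, ddof=1)
    if n_variable is not None and n_variable < feats.shape[1]:
        chosen = variances.sort_values(ascending=False, kind="mergesort").index[:n_variable]
        feats = feats[chosen]
        variances = variances[chosen]

    const = variances == 0.0
    tested = feats.loc[:, ~const.to_numpy(bool)]
    n = len(window)
    xv = tested.to_numpy(float)
    dz = dist - dist.mean()
    xz = xv - xv.mean(axis=0)
    r = (xz.T @ dz) / (np.linalg.norm(xz, axis=0) * np.linalg.norm(dz))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p_adj = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

    result = pd.DataFrame(
        {"r": r, "p": p, "p_adj": p_adj, "n": n, "constant": False},
        index=tested.columns,
    )
    if const.any():
        excluded = pd.DataFrame(
            {"r": np.nan, "p": np.nan, "p_adj": np.nan, "n": n, "constant": True},
            index=variances.index[const],
        )
        result = pd.concat([result, excluded])
    result.index.name = "feature"
    return result
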