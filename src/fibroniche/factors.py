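"""Non-negative matrix factorization of spot expression and factor-level
summaries.

The spots × genes normalized matrix X is factorized as X ≈ W Hᵀ with
W ≥ 0 the per-spot factor *activities* (spots × K) and H ≥ 0 the gene
*loadings/weights* (genes × K). The optimizer is classic Frobenius
multiplicative updates from a deterministic NNDSVDa initialization, which
gives three contract properties downstream stages rely on: strict
determinism for a given input, non-negativity, and a non-increasing
per-iteration objective trace.

Factor summaries follow the study conventions: top-n contributing genes
with min–max scaled weights; F^hi spot selection at the 99th activity
percentile (strict ">" against a linear-interpolation quantile) or as the
top-n ranked spots per sample; per-group prevalence/detection summaries;
and PCA → shared-nearest-neighbor → modularity subclustering of selected
spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

_EPS = 1e-12


@dataclass
class FactorModel:
    activities: pd.DataFrame  # spots x K, non-negative
    loadings: pd.DataFrame  # genes x K, non-negative
    k: int
    objective_trace: np.ndarray  # Frobenius reconstruction error per iteration
    seed: int
    n_iter: int


@dataclass
class FactorGeneRanking:
    """Per-factor ordered gene lists with raw and min–max scaled weights."""

    per_factor: dict[str, pd.DataFrame]  # columns: weight, scaled_weight
    n: int

    def gene_sets(self) -> dict[str, set]:
        return {f: set(df.index) for f, df in self.per_factor.items()}


def _nndsvda_init(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic non-negative SVD initialization (zeros filled with the
    matrix mean, the 'a' variant)."""
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    w = np.zeros((x.shape[0], k))
    h = np.zeros((k, x.shape[1]))
    w[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    h[0, :] = np.sqrt(s[0]) * np.abs(vt[0, :])
    for j in range(1, k):
        uj, vj = u[:, j], vt[j, :]
        up, un = np.maximum(uj, 0), np.maximum(-uj, 0)
        vp, vn = np.maximum(vj, 0), np.maximum(-vj, 0)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        mp, mn = n_up * n_vp, n_un * n_vn
        if mp >= mn and mp > 0:
            w[:, j] = np.sqrt(s[j] * mp) * up / n_up
            h[j, :] = np.sqrt(s[j] * mp) * vp / n_vp
        elif mn > 0:
            w[:, j] = np.sqrt(s[j] * mn) * un / n_un
            h[j, :] = np.sqrt(s[j] * mn) * vn / n_vn
    mean = x.mean()
    w[w == 0] = mean
    h[h == 0] = mean
    return w, h


def fit_nmf(
    norm: pd.DataFrame,
    k: int = 30,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> FactorModel:
    """Factorize a non-negative matrix into K factors.

    Stops at ``max_iter`` or when the relative objective decrease falls
    below ``tol``. The initialization is fully deterministic, so the seed
    only tags the model for provenance; identical input always yields an
    identical model.
    """
    x = norm.to_numpy(float)
    if (x < 0).any():
        raise ValueError("NMF input must be non-negative")
    if k < 1 or k > min(x.shape):
        raise ValueError(f"k must be in [1, {min(x.shape)}]")
    w, h = _nndsvda_init(x, k)
    trace = [float(np.linalg.norm(x - w @ h))]
    for it in range(max_iter):
        h *= (w.T @ x) / (w.T @ w @ h + _EPS)
        w *= (x @ h.T) / (w @ (h @ h.T) + _EPS)
        err = float(np.linalg.norm(x - w @ h))
        trace.append(err)
        if trace[-2] - err < tol * max(trace[-2], _EPS):
            break
    names = [f"F{j + 1}" for j in range(k)]
    return FactorModel(
        activities=pd.DataFrame(w, index=norm.index, columns=names),
        loadings=pd.DataFrame(h.T, index=norm.columns, columns=names),
        k=k,
        objective_trace=np.asarray(trace),
        seed=seed,
        n_iter=len(trace) - 1,
    )


def top_factor_genes(model: FactorModel, n: int = 100) -> FactorGeneRanking:
    """Top-n contributing genes per factor, ordered strictly by descending
    raw weight (ties broken by gene id), with weights min–max scaled to
    [0, 1] over the selected n. When all selected weights are equal and
    nonzero the scaled weights are defined as 1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    n_genes = model.loadings.shape[0]
    if n > n_genes:
        warnings.warn(f"n={n} exceeds the {n_genes} available genes; clipping")
        n = n_genes
    out = {}
    for f in model.loadings.columns:
        w = model.loadings[f]
        order = sorted(w.index, key=lambda g: (-w[g], g))[:n]
        sel = w.loc[order]
        lo, hi = float(sel.min()), float(sel.max())
        if hi > lo:
            scaled = (sel - lo) / (hi - lo)
        else:
            scaled = pd.Series(1.0 if hi > 0 else 0.0, index=sel.index)
        out[f] = pd.DataFrame({"weight": sel, "scaled_weight": scaled})
    return FactorGeneRanking(per_factor=out, n=n)


def select_high_spots(
    model: FactorModel,
    factor: str,
    mode: str = "percentile",
    q: float = 99.0,
    n: int = 100,
    scope: str = "dataset",
    sample_ids: pd.Series | None = None,
) -> pd.Index:
    """F^hi spot selection for one factor.

    Percentile mode: spots with activity strictly above the linear-
    interpolation quantile at ``q`` over the scope (dataset-wide or per
    sample). Top-n mode: the n highest-activity spots per scope unit, ties
    broken by spot id.
    """
    if factor not in model.activities.columns:
        raise ValueError(f"unknown factor {factor!r}")
    act = model.activities[factor]
    if scope not in {"dataset", "per_sample"}:
        raise ValueError("scope must be 'dataset' or 'per_sample'")
    if scope == "per_sample":
        if sample_ids is None:
            raise ValueError("per_sample scope requires sample_ids")
        groups = [g for _, g in act.groupby(sample_ids.reindex(act.index), observed=True)]
    else:
        groups = [act]

    selected: list = []
    for g in groups:
        if mode == "percentile":
            if not 0 < q < 100:
                raise ValueError("q must be in (0, 100)")
            thr = float(np.quantile(g.to_numpy(float), q / 100.0))
            selected.extend(g.index[g > thr])
        elif mode == "top_n":
            if n > len(g):
                warnings.warn(f"top_n={n} exceeds {len(g)} spots in scope; returning all")
            order = sorted(g.index, key=lambda s: (-g[s], s))[:n]
            selected.extend(order)
        else:
            raise ValueError("mode must be 'percentile' or 'top_n'")
    return pd.Index(selected, name="spot_id")


def factor_region_summary(
    model: FactorModel,
    groups: pd.Series,
    q: float = 99.0,
) -> pd.DataFrame:
    """Per factor × group: F^hi frequency (|F^hi ∩ group| / |group|), mean
    z-scaled activity, and detection rate (% of group spots with activity
    above the factor's dataset mean). Empty groups are reported with
    frequency 0 and a flag."""
    groups = groups.reindex(model.activities.index)
    rows = []
    group_levels = sorted(groups.dropna().unique())
    for f in model.activities.columns:
        act = model.activities[f]
        sd = float(act.std(ddof=0))
        z = (act - act.mean()) / sd if sd > 0 else act * 0.0
        fhi = set(select_high_spots(model, f, mode="percentile", q=q))
        for g in group_levels:
            members = groups.index[groups == g]
            empty = len(members) == 0
            rows.append(
                {
                    "factor": f,
                    "group": g,
                    "n_spots": len(members),
                    "fhi_frequency": 0.0 if empty else len(fhi & set(members)) / len(members),
                    "mean_z_activity": np.nan if empty else float(z.loc[members].mean()),
                    "detection_rate": np.nan if empty else
                        float((act.loc[members] > act.mean()).mean() * 100.0),
                    "empty_group": empty,
                }
            )
    return pd.DataFrame(rows)


def snn_graph(x: np.ndarray, ids, n_neighbors: int, prune: float = 1.0 / 15.0) -> nx.Graph:
    """Shared-nearest-neighbor graph: nodes are spots, edges between kNN
    pairs weighted by the Jaccard overlap of their neighbor sets, pruned
    below ``prune`` (the Seurat-style construction)."""
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(x)
    _, idx = nn.kneighbors(x)
    neigh = [set(row) for row in idx]
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, row in enumerate(idx):
        for j in row:
            if j == i:
                continue
            a, b = neigh[i], neigh[int(j)]
            w = len(a & b) / len(a | b)
            if w >= prune:
                g.add_edge(ids[i], ids[int(j)], weight=w)
    return g


def subcluster_spots(
    norm_subset: pd.DataFrame,
    n_pcs: int = 8,
    resolution: float = 0.4,
    n_neighbors: int = 20,
    seed: int = 0,
) -> pd.Series:
    """PCA → SNN graph → Louvain modularity communities on a spot subset.

    Deterministic under a fixed seed; cluster ids are relabeled by size
    (descending, ties by smallest member id) starting at 0.
    """
    if len(norm_subset) < n_neighbors + 1:
        raise ValueError(
            f"subset of {len(norm_subset)} spots is too small for "
            f"n_neighbors={n_neighbors}; use a smaller n_neighbors"
        )
    x = norm_subset.to_numpy(float)
    x = x - x.mean(axis=0)
    n_comp = min(n_pcs, min(x.shape) - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(x)
    g = snn_graph(pcs, list(norm_subset.index), n_neighbors=n_neighbors)
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted((set(c) for c in comms), key=lambda c: (-len(c), min(c)))
    labels = pd.Series(index=norm_subset.index, dtype=int, name="cluster")
    for lab, members in enumerate(comms):
        labels.loc[list(members)] = lab
    return labels


class SpotNMF(BaseEstimator):
    """sklearn-style estimator over :func:`fit_nmf`.

    ``fit`` stores ``components_`` (K × genes loadings) plus the fitted
    activities; ``transform`` solves for activities of new spots with the
    loadings held fixed (multiplicative updates on W only).
    """

    def __init__(self, k: int = 30, seed: int = 0, max_iter: int = 500, tol: float = 1e-5):
        self.k = k
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: pd.DataFrame, y=None):
        model = fit_nmf(X, k=self.k, seed=self.seed, max_iter=self.max_iter, tol=self.tol)
        self.model_ = model
        self.components_ = model.loadings.to_numpy().T
        self.activities_ = model.activities
        self.objective_trace_ = model.objective_trace
        self.n_iter_ = model.n_iter
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise ValueError("SpotNMF is not fitted")
        x = np.asarray(X, dtype=float)
        h = self.components_
        w = np.full((x.shape[0], self.k), x.mean() + _EPS)
        for _ in range(200):
            w *= (x @ h.T) / (w @ (h @ h.T) + _EPS)
        return w

    def fit_transform(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).activities_.to_numpy()


class SpotSubclusterer(BaseEstimator):
    """sklearn-style wrapper over :func:`subcluster_spots`."""

    def __init__(self, n_pcs: int = 8, resolution: float = 0.4,
                 n_neighbors: int = 20, seed: int = 0):
        self.n_pcs = n_pcs
        self.resolution = resolution
        self.n_neighbors = n_neighbors
        self.seed = seed

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.Series:
        self.labels_ = subcluster_spots(
            X, n_pcs=self.n_pcs, resolution=self.resolution,
            n_neighbors=self.n_neighbors, seed=self.seed,
        )
        return self.labels_

    def fit(self, X: pd.DataFrame, y=None):
        self.fit_predict(X)
        return self
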