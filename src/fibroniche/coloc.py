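"""Factor↔cell-type colocalization, compartmentalization of cell types, and
cross-species factor matching.

Colocalization is plain pairwise Pearson correlation between spot factor
activities and inferred cell-type densities. Compartments are found by
hierarchically clustering cell types on the distance ``1 − r`` between
their density vectors (range [0, 2], so anticorrelated types never
co-compartmentalize) and cutting the dendrogram at height h (default 1.5).
Cross-species factor similarity is the Jaccard index over top contributing
gene sets, with an ortholog map bridging namespaces; pairs above 0.1 are
flagged as major overlaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .factors import FactorGeneRanking, FactorModel


def factor_celltype_correlation(
    model: FactorModel,
    densities: pd.DataFrame,
    group_by: pd.Series | None = None,
) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """Pearson r between each factor's activity and each cell type's
    density over the shared spots (per group when ``group_by`` given).

    Constant columns yield NaN entries (undefined correlation) rather than
    an error.
    """
    shared = model.activities.index.intersection(densities.index)
    if len(shared) == 0:
        raise ValueError("factor activities and densities share no spots")
    act = model.activities.loc[shared]
    dens = densities.loc[shared]

    def corr_block(a: pd.DataFrame, d: pd.DataFrame) -> pd.DataFrame:
        if len(a) < 3:
            raise ValueError("need at least 3 spots per group for correlation")
        av, dv = a.to_numpy(float), d.to_numpy(float)
        az = av - av.mean(axis=0)
        dz = dv - dv.mean(axis=0)
        sa = az.std(axis=0)
        sd = dz.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (az.T @ dz) / len(a) / np.outer(sa, sd)
        r[~np.isfinite(r)] = np.nan
        return pd.DataFrame(np.clip(r, -1, 1), index=a.columns, columns=d.columns)

    if group_by is None:
        return corr_block(act, dens)
    groups = group_by.reindex(shared)
    return {
        g: corr_block(act.loc[idx.index], dens.loc[idx.index])
        for g, idx in groups.dropna().groupby(groups, observed=True)
    }


@dataclass
class CompartmentPartition:
    """Cell-type → compartment assignment from a dendrogram cut."""

    assignments: pd.Series  # cell_type -> compartment id ("A", "B", ...)
    merge_heights: np.ndarray
    h: float
    linkage_method: str
    dropped: list[str]

    def members(self) -> dict[str, list[str]]:
        return {
            c: sorted(self.assignments.index[self.assignments == c])
            for c in sorted(self.assignments.unique())
        }


def _letters(i: int) -> str:
    label = ""
    while True:
        label = chr(ord("A") + i % 26) + label
        i = i // 26 - 1
        if i < 0:
            return label


def celltype_compartments(
    densities: pd.DataFrame,
    h: float = 1.5,
    linkage_method: str = "complete",
    exclude_patterns: tuple[str, ...] = ("NA", "low.quality"),
) -> CompartmentPartition:
    """Cut a 1−r correlation dendrogram over cell types at height h.

    Cell types whose names contain an excluded pattern are dropped first;
    constant columns are dropped with a warning (undefined correlation).
    Compartment ids are letters ordered by compartment size (descending,
    ties by first member name).
    """
    if linkage_method not in {"complete", "average"}:
        raise ValueError("linkage must be 'complete' or 'average'")
    dropped = [c for c in densities.columns
               if any(p in str(c) for p in exclude_patterns)]
    dens = densities.drop(columns=dropped)
    const = [c for c in dens.columns if float(dens[c].std()) == 0.0]
    if const:
        warnings.warn(f"dropping constant density columns: {const}")
        dropped += const
        dens = dens.drop(columns=const)
    if dens.shape[1] < 1:
        raise ValueError("no cell types left after exclusions")
    if dens.shape[0] < 3:
        raise ValueError("need at least 3 spots")
    if dens.shape[1] == 1:
        return CompartmentPartition(
            assignments=pd.Series("A", index=dens.columns, name="compartment"),
            merge_heights=np.empty(0), h=h, linkage_method=linkage_method,
            dropped=dropped,
        )
    r = np.corrcoef(dens.to_numpy(float).T)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(np.clip(dist, 0, None), checks=False), method=linkage_method)
    # strict cut: types co-compartmentalize only when merged strictly below
    # h (a pair at exactly the cutoff stays separate); the 1e-9 margin only
    # absorbs float jitter in the correlation distances
    flat = fcluster(z, t=h - 1e-9, criterion="distance")
    raw = pd.Series(flat, index=dens.columns)
    order = sorted(raw.unique(), key=lambda c: (-(raw == c).sum(), min(raw.index[raw == c])))
    rename = {c: _letters(i) for i, c in enumerate(order)}
    return CompartmentPartition(
        assignments=raw.map(rename).rename("compartment"),
        merge_heights=z[:, 2].copy(),
        h=h,
        linkage_method=linkage_method,
        dropped=dropped,
    )


def compartment_scores(
    densities: pd.DataFrame, partition: CompartmentPartition
) -> pd.DataFrame:
    """Spot-wise compartment scores: the sum of inferred densities over the
    cell types of each compartment. Row sums equal each spot's total
    density over the partitioned cell types."""
    missing = set(partition.assignments.index) - set(densities.columns)
    if missing:
        raise ValueError(f"partition covers unknown cell types: {sorted(missing)}")
    out = {}
    for comp, members in partition.members().items():
        out[comp] = densities[members].sum(axis=1)
    return pd.DataFrame(out, index=densities.index)


def resolve_ortholog_map(ortholog_map: pd.DataFrame) -> dict[str, str]:
    """Two-column (gene_a, gene_b) table → mapping of b-namespace genes
    into a's. One-to-many rows collapse to the first pair after a
    deterministic sort; collapses are logged via warning."""
    m = ortholog_map.iloc[:, :2].astype(str)
    m.columns = ["gene_a", "gene_b"]
    m = m.sort_values(["gene_b", "gene_a"], kind="mergesort")
    dup = m["gene_b"].duplicated(keep=False)
    if dup.any():
        warnings.warn(
            f"{m.loc[dup, 'gene_b'].nunique()} genes map to multiple orthologs; "
            "keeping the first listed pair"
        )
    m = m.drop_duplicates("gene_b", keep="first")
    return dict(zip(m["gene_b"], m["gene_a"]))


def cross_factor_jaccard(
    ranking_a: FactorGeneRanking,
    ranking_b: FactorGeneRanking,
    ortholog_map: pd.DataFrame | None = None,
    min_jaccard: float = 0.1,
) -> pd.DataFrame:
    """Jaccard index |A∩B| / |A∪B| over the top-gene sets of every factor
    pair.

    Genes of b are mapped through the ortholog map when given; unmapped
    genes stay in the union but can never enter the intersection. Pairs
    with Jaccard > ``min_jaccard`` are flagged as major overlaps.
    """
    if ranking_a.n != ranking_b.n:
        raise ValueError("rankings must be built with the same n")
    mapping = resolve_ortholog_map(ortholog_map) if ortholog_map is not None else None
    sets_a = ranking_a.gene_sets()
    rows = []
    for fb, genes_b in ranking_b.gene_sets().items():
        if mapping is None:
            mapped, unmapped = set(genes_b), set()
        else:
            mapped = {mapping[g] for g in genes_b if g in mapping}
            unmapped = {g for g in genes_b if g not in mapping}
        for fa, genes_a in sets_a.items():
            inter = len(genes_a & mapped)
            union = len(genes_a | mapped | unmapped)
            jac = inter / union if union else 0.0
            rows.append(
                {
                    "factor_a": fa,
                    "factor_b": fb,
                    "intersection": inter,
                    "union": union,
                    "jaccard": jac,
                    "major_overlap": jac > min_jaccard,
                }
            )
    return pd.DataFrame(rows).sort_values(["factor_a", "factor_b"]).reset_index(drop=True)


class CellTypeCompartments(BaseEstimator):
    """sklearn-style wrapper over :func:`celltype_compartments` /
    :func:`compartment_scores`: ``fit`` learns the partition from a density
    matrix, ``transform`` produces spot-wise compartment scores."""

    def __init__(self, h: float = 1.5, linkage_method: str = "complete",
                 exclude_patterns: tuple[str, ...] = ("NA", "low.quality")):
        self.h = h
        self.linkage_method = linkage_method
        self.exclude_patterns = exclude_patterns

    def fit(self, X: pd.DataFrame, y=None):
        self.partition_ = celltype_compartments(
            X, h=self.h, linkage_method=self.linkage_method,
            exclude_patterns=self.exclude_patterns,
        )
        self.labels_ = self.partition_.assignments
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return compartment_scores(X, self.partition_)
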