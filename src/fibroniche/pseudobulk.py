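"""Pseudobulk aggregation, a simplified differential-expression test, and
cross-species DEG overlap.

Pseudobulk profiles are exact integer sums of raw counts over all spots of
a donor/animal (optionally restricted to annotated region labels). The DE
test is deliberately simple — per-gene Welch t-test on log2 counts-per-
million with a pseudocount, BH-corrected — because the pipeline's tested
claims concern aggregation conservation, set logic and calibration, not
dispersion modeling; externally produced DE tables with the same schema
(gene, log2fc, p, p_adj) can be injected for the overlap analysis.

Cross-species overlap restricts both tables to the shared ortholog-mapped
gene universe, reports per-side significant sets, their intersection, and
the sign-discordant subset (shared significance, opposite fold-change
direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coloc import resolve_ortholog_map


def aggregate_pseudobulk(
    counts: pd.DataFrame,
    grouping: pd.Series,
    annotation: pd.Series | None = None,
    region_labels: set | None = None,
) -> pd.DataFrame:
    """Sum raw counts per gene across all spots of each group.

    When ``region_labels`` is given, spots are first restricted to those
    annotated with one of the labels (an empty selection is an error, not
    an empty matrix). Spots without a group assignment are an error.
    """
    sub = counts
    if region_labels is not None:
        if annotation is None:
            raise ValueError("region_labels requires an annotation")
        keep = annotation.index[annotation.isin(region_labels)]
        sub = counts.loc[counts.index.intersection(keep)]
        if sub.empty:
            raise ValueError(f"no spots annotated with {sorted(region_labels)}")
    g = grouping.reindex(sub.index)
    if g.isna().any():
        bad = list(sub.index[g.isna()][:5])
        raise ValueError(f"spots without a group assignment: {bad}")
    pb = sub.groupby(g, observed=True).sum()
    pb.index.name = "group"
    return pb.astype(np.int64)


@dataclass
class DEResult:
    table: pd.DataFrame  # index gene; columns log2fc, p, p_adj, mean_case, mean_control

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "DEResult":
        required = {"log2fc", "p", "p_adj"}
        if not required <= set(table.columns):
            raise ValueError(f"DE table needs columns {sorted(required)}")
        return cls(table=table)


def simple_de(
    pb: pd.DataFrame,
    condition: pd.Series,
    pseudocount: float = 1.0,
) -> DEResult:
    """Two-condition DE on pseudobulk profiles.

    Counts are scaled to CPM per group; log2FC = log2((mean_case + pc) /
    (mean_control + pc)) on mean CPM; the p-value is a two-sided
    unequal-variance t-test on log2(CPM + pc) across groups, BH-corrected
    over all tested genes.
    """
    cond = condition.reindex(pb.index)
    if cond.isna().any():
        raise ValueError("every pseudobulk group needs a condition")
    bad = set(cond.unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"conditions must be 'case'/'control', got {sorted(bad)}")
    case = pb.index[cond == "case"]
    ctrl = pb.index[cond == "control"]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need at least 2 replicates per condition")
    cpm = pb.div(pb.sum(axis=1), axis=0) * 1e6
    logcpm = np.log2(cpm + pseudocount)
    a = logcpm.loc[case].to_numpy(float)
    b = logcpm.loc[ctrl].to_numpy(float)
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    diff = a.mean(axis=0) - b.mean(axis=0)
    p = np.where(np.isnan(p), np.where(diff == 0.0, 1.0, 0.0), p)
    mean_case = cpm.loc[case].mean(axis=0)
    mean_ctrl = cpm.loc[ctrl].mean(axis=0)
    log2fc = np.log2((mean_case + pseudocount) / (mean_ctrl + pseudocount))
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "p_adj": multipletests(p, method="fdr_bh")[1],
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
        },
        index=pb.columns,
    )
    table.index.name = "gene"
    return DEResult(table=table)


def cross_species_overlap(
    de_a: DEResult,
    de_b: DEResult,
    ortholog_map: pd.DataFrame | None = None,
    alpha: float = 0.05,
    lfc_threshold: float = 0.0,
) -> dict:
    """Overlap of significant DEGs between two DE analyses.

    Table b's genes are mapped into a's namespace through the ortholog map
    (identity when None); the universe is the set of genes present in both
    tables after mapping. Significance: p_adj < alpha and |log2FC| >
    lfc_threshold. The discordant subset holds genes significant on both
    sides with strictly opposite fold-change signs.
    """
    ta = de_a.table
    tb = de_b.table.copy()
    if ortholog_map is not None:
        mapping = resolve_ortholog_map(ortholog_map)
        tb = tb.loc[tb.index.isin(mapping)]
        tb.index = [mapping[g] for g in tb.index]
        tb = tb[~tb.index.duplicated(keep="first")]
    universe = ta.index.intersection(tb.index)
    if len(universe) == 0:
        raise ValueError("empty shared gene universe")
    ta, tb = ta.loc[universe], tb.loc[universe]

    def sig(t: pd.DataFrame) -> pd.Index:
        return t.index[(t["p_adj"] < alpha) & (t["log2fc"].abs() > lfc_threshold)]

    sig_a, sig_b = set(sig(ta)), set(sig(tb))
    inter = sig_a & sig_b
    discordant = {g for g in inter if ta.loc[g, "log2fc"] * tb.loc[g, "log2fc"] < 0}
    return {
        "universe_size": int(len(universe)),
        "significant_a": sorted(sig_a),
        "significant_b": sorted(sig_b),
        "intersection": sorted(inter),
        "discordant": sorted(discordant),
        "n_significant_a": len(sig_a),
        "n_significant_b": len(sig_b),
        "n_intersection": len(inter),
        "n_discordant": len(discordant),
    }
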