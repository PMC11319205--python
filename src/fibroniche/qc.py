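"""Spot/gene quality filtering and log-CP10K normalization.

The filter thresholds mirror the study presets for human (350 UMIs/spot,
100 UMIs/gene, 10 genes/spot, 5 spots/gene, 30% mitochondrial/hemoglobin
cap) and mouse (300 UMIs/spot, no min-genes-per-spot) Visium sections.
Filtering applies, in fixed order, (1) gene filters, (2) spot filters on
the gene-filtered matrix, (3) the mito/hemo fraction computed on the
matrix as it entered the round — and iterates that round to a fixpoint so
the operation is idempotent (spot removal changes gene totals, so a single
pass is not).

Normalization is log1p of counts scaled to 10,000 per spot: a documented
variance-stabilizing stand-in chosen because every downstream statistic in
scope (NMF, Pearson correlations) only needs a non-negative, depth-
corrected matrix. Batch/donor regression is out of scope and flagged when
multiple samples are present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .schemas import validate_counts

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    min_umis_per_spot: int = 350
    min_umis_per_gene: int = 100
    min_genes_per_spot: int = 10
    min_spots_per_gene: int = 5
    max_mito_hemo_fraction: float = 0.30
    mito_patterns: tuple[str, ...] = ("MT-",)
    hemo_patterns: tuple[str, ...] = ("HBA", "HBB")
    # "sum": remove when mito+hemo fraction exceeds the cap (most
    # conservative, subsumes the per-family checks); "each": per family only
    fraction_mode: str = "sum"

    def __post_init__(self):
        for name in ("min_umis_per_spot", "min_umis_per_gene",
                     "min_genes_per_spot", "min_spots_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.max_mito_hemo_fraction <= 1.0:
            raise ValueError("max_mito_hemo_fraction must be in [0, 1]")
        if self.fraction_mode not in {"sum", "each"}:
            raise ValueError("fraction_mode must be 'sum' or 'each'")


HUMAN_PRESET = QCThresholds()
MOUSE_PRESET = QCThresholds(
    min_umis_per_spot=300,
    min_genes_per_spot=0,
    mito_patterns=("mt-",),
    hemo_patterns=("Hba", "Hbb"),
)

PRESETS = {"human": HUMAN_PRESET, "mouse": MOUSE_PRESET}


def _family_fraction(counts: pd.DataFrame, patterns: tuple[str, ...],
                     symbols: pd.Series | None) -> pd.Series:
    names = symbols.reindex(counts.columns).fillna("") if symbols is not None \
        else pd.Series(counts.columns, index=counts.columns)
    mask = names.astype(str).str.startswith(tuple(patterns)) if patterns else \
        pd.Series(False, index=counts.columns)
    totals = counts.sum(axis=1)
    fam = counts.loc[:, mask.to_numpy(bool)].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = fam / totals
    return frac.fillna(0.0)


def filter_matrix(
    counts: pd.DataFrame,
    thresholds: QCThresholds = HUMAN_PRESET,
    gene_symbols: pd.Series | None = None,
    chromosomes: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply spot/gene quality filters; returns (filtered counts, QCReport).

    ``gene_symbols`` maps gene id → symbol for the mito/hemo prefix match
    (column names are matched directly when absent). ``chromosomes`` is an
    optional gene → chromosome table; X/Y genes are removed when provided.
    Raises if the result would have no spots or no genes.
    """
    if counts.empty:
        raise ValueError("counts matrix is empty")
    validate_counts(counts)
    t = thresholds
    report: dict = {"rounds": [], "sex_genes_removed": 0}

    if chromosomes is not None:
        chrom = chromosomes.reindex(counts.columns).astype(str).str.upper()
        sex = chrom.isin({"X", "Y", "CHRX", "CHRY"})
        report["sex_genes_removed"] = int(sex.sum())
        counts = counts.loc[:, ~sex.to_numpy(bool)]

    current = counts
    while True:
        entry = current  # fractions for this round use the pre-gene-filter matrix
        step: dict = {}

        gene_tot = entry.sum(axis=0)
        gene_spots = (entry > 0).sum(axis=0)
        keep_genes = (gene_tot >= t.min_umis_per_gene) & (gene_spots >= t.min_spots_per_gene)
        step["genes_removed"] = int((~keep_genes).sum())
        current = entry.loc[:, keep_genes.to_numpy(bool)]

        spot_tot = current.sum(axis=1)
        spot_genes = (current > 0).sum(axis=1)
        keep_spots = (spot_tot >= t.min_umis_per_spot) & (spot_genes >= t.min_genes_per_spot)
        step["spots_removed_depth"] = int((~keep_spots).sum())

        mito = _family_fraction(entry, t.mito_patterns, gene_symbols)
        hemo = _family_fraction(entry, t.hemo_patterns, gene_symbols)
        if t.fraction_mode == "sum":
            frac_bad = (mito + hemo) > t.max_mito_hemo_fraction
        else:
            frac_bad = (mito > t.max_mito_hemo_fraction) | (hemo > t.max_mito_hemo_fraction)
        frac_bad = frac_bad.reindex(current.index, fill_value=False)
        step["spots_removed_mito_hemo"] = int((keep_spots & frac_bad).sum())
        keep_spots &= ~frac_bad
        current = current.loc[keep_spots.to_numpy(bool)]

        report["rounds"].append(step)
        changed = step["genes_removed"] or step["spots_removed_depth"] \
            or step["spots_removed_mito_hemo"]
        if not changed:
            break

    if current.shape[0] == 0:
        raise ValueError("QC filtering removed all spots (empty result)")
    if current.shape[1] == 0:
        raise ValueError("QC filtering removed all genes (empty result)")
    report["n_spots"] = int(current.shape[0])
    report["n_genes"] = int(current.shape[1])
    return current, report


def normalize_log_cp10k(counts: pd.DataFrame) -> pd.DataFrame:
    """log1p(10,000 × count / spot total); zero-total spots must be
    filtered beforehand."""
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0][:5])
        raise ValueError(f"zero-total spots present (e.g. {bad}); run filter_matrix first")
    vals = counts.to_numpy(float)
    norm = np.log1p(1e4 * vals / totals.to_numpy(float)[:, None])
    return pd.DataFrame(norm, index=counts.index, columns=counts.columns)


class QCFilter(BaseEstimator, TransformerMixin):
    """Estimator wrapper around :func:`filter_matrix`.

    ``fit`` learns the surviving spot/gene sets; ``transform`` restricts a
    matrix to them, so the filter composes with sklearn pipelines.
    """

    def __init__(self, thresholds: QCThresholds = HUMAN_PRESET):
        self.thresholds = thresholds

    def fit(self, X: pd.DataFrame, y=None):
        filtered, report = filter_matrix(X, self.thresholds)
        self.kept_spots_ = filtered.index
        self.kept_genes_ = filtered.columns
        self.report_ = report
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[X.index.intersection(self.kept_spots_),
                     X.columns.intersection(self.kept_genes_)]


class LogCP10K(BaseEstimator, TransformerMixin):
    """Stateless log-CP10K normalizer (estimator form of
    :func:`normalize_log_cp10k`)."""

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return normalize_log_cp10k(X)
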