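"""Synthetic Visium-like sections with known ground truth.

The generator emulates the structure the downstream analyses assume:

* a hexagonal capture-spot lattice at ~100 µm pitch (even rows at
  ``x = col·pitch``, odd rows offset by ``pitch/2``, rows ``pitch·√3/2``
  apart);
* annotated circular histology regions (e.g. fibroblastic foci on an
  alveolar background);
* spot expression driven by K non-negative factors — each factor is a
  smooth spatial activity field (a Gaussian bump anchored on a region or a
  background locus) paired with a block of dedicated genes — with counts
  drawn Poisson around the rate ``activities @ loadings.T`` scaled to a
  target library size (an optional negative-binomial dispersion covers the
  overdispersion of real data, default off);
* cell-type densities linked to the factors through a non-negative mixing
  matrix plus noise;
* cluster labels planted with distance-dependent enrichment at region
  borders, for calibrating and powering the enrichment statistic.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PITCH_UM = 100.0
SPOT_DIAMETER_UM = 55.0  # metadata only; analyses use spot centers
FOCUS_LABEL = "fibroblastic foci/fibrous tissue"
BACKGROUND_LABEL = "within normal limits (alveolar)"


@dataclass
class Region:
    """A circular annotated region: union members share a label."""

    label: str
    center: tuple[float, float]
    radius_um: float


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated section."""

    factor_loadings_true: pd.DataFrame  # genes x K
    factor_activities_true: pd.DataFrame  # spots x K
    rate_matrix: pd.DataFrame  # spots x genes, pre-noise Poisson rates
    regions: list[Region] = field(default_factory=list)
    density_mixing: pd.DataFrame | None = None  # cell_type x K
    seed: int = 0


def hex_lattice(
    n_rows: int, n_cols: int, pitch_um: float = DEFAULT_PITCH_UM, sample_id: str = "synthetic_0"
) -> pd.DataFrame:
    """Regular hexagonal SpotGrid with ``n_rows × n_cols`` spots."""
    if n_rows < 2 or n_cols < 2:
        raise ValueError("n_rows and n_cols must be >= 2")
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    x = cols * pitch_um + np.where(rows % 2 == 1, pitch_um / 2.0, 0.0)
    y = rows * pitch_um * np.sqrt(3.0) / 2.0
    ids = [f"{sample_id}:r{r:03d}c{c:03d}" for r, c in zip(rows, cols)]
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "x_um": x,
            "y_um": y,
            "array_row": rows,
            "array_col": cols,
            "in_tissue": True,
        },
        index=pd.Index(ids, name="spot_id"),
    )


def _coerce_regions(region_spec, pitch_um: float) -> list[Region]:
    regions = []
    for r in region_spec or []:
        if isinstance(r, Region):
            regions.append(r)
        elif isinstance(r, dict):
            regions.append(Region(r["label"], tuple(r["center"]), float(r["radius_um"])))
        else:
            label, center, radius = r
            regions.append(Region(label, tuple(center), float(radius)))
    for r in regions:
        if r.radius_um < pitch_um:
            raise ValueError(f"region {r.label!r}: radius must be >= pitch")
    return regions


def annotate_regions(
    grid: pd.DataFrame, regions: list[Region], background_label: str = BACKGROUND_LABEL
) -> pd.Series:
    """Per-spot labels: disk membership by spot center, later regions win."""
    labels = pd.Series(background_label, index=grid.index, name="label")
    xy = grid[["x_um", "y_um"]].to_numpy(float)
    for r in regions:
        inside = np.hypot(xy[:, 0] - r.center[0], xy[:, 1] - r.center[1]) <= r.radius_um
        labels.iloc[np.flatnonzero(inside)] = r.label
    return labels


def simulate_section(
    n_rows: int = 20,
    n_cols: int = 20,
    pitch_um: float = DEFAULT_PITCH_UM,
    n_genes: int = 200,
    k: int = 5,
    region_spec: list | None = None,
    library_size_mean: float = 5000.0,
    seed: int = 0,
    sample_id: str = "synthetic_0",
    nb_dispersion: float = 0.0,
    baseline_activity: float = 0.05,
    n_cell_types: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series, SyntheticTruth]:
    """Simulate one Visium-like section.

    Returns ``(grid, counts, densities, annotation, truth)``. The first
    ``len(region_spec)`` factors are anchored on the planted regions (their
    activity is a Gaussian bump over the region); remaining factors get
    seeded background loci. Genes are split into K equal blocks with
    uniform(0.5, 1.5) weights inside their block and zero outside, so the
    noiseless rate matrix has rank exactly K.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_genes:
        raise ValueError("k must not exceed n_genes")
    rng = np.random.default_rng(seed)
    grid = hex_lattice(n_rows, n_cols, pitch_um, sample_id)
    xy = grid[["x_um", "y_um"]].to_numpy(float)
    xmin, xmax = xy[:, 0].min(), xy[:, 0].max()
    ymin, ymax = xy[:, 1].min(), xy[:, 1].max()

    regions = _coerce_regions(region_spec, pitch_um)
    for r in regions:
        if not (xmin <= r.center[0] <= xmax and ymin <= r.center[1] <= ymax):
            raise ValueError(f"region {r.label!r} center outside the lattice bounding box")

    # factor activity fields: Gaussian bumps on a small baseline
    activities = np.full((len(grid), k), baseline_activity)
    centers, widths = [], []
    for r in regions[:k]:
        centers.append(r.center)
        widths.append(r.radius_um / 1.5)
    # background factor loci: fixed well-separated fractions of the bounding
    # box, so planted factors stay spatially distinguishable
    locus_fracs = [(0.2, 0.2), (0.8, 0.8), (0.8, 0.2), (0.2, 0.8), (0.5, 0.5),
                   (0.5, 0.15), (0.15, 0.5), (0.85, 0.5), (0.5, 0.85), (0.35, 0.35)]
    li = 0
    while len(centers) < k:
        fx, fy = locus_fracs[li % len(locus_fracs)]
        jitter = rng.uniform(-0.03, 0.03, size=2)
        centers.append((xmin + (fx + jitter[0]) * (xmax - xmin),
                        ymin + (fy + jitter[1]) * (ymax - ymin)))
        widths.append(3.0 * pitch_um)
        li += 1
    for j, ((cx, cy), w) in enumerate(zip(centers, widths)):
        d2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
        activities[:, j] += np.exp(-d2 / (2.0 * w**2))

    # block-structured gene loadings
    gene_ids = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    loadings = np.zeros((n_genes, k))
    blocks = np.array_split(np.arange(n_genes), k)
    for j, block in enumerate(blocks):
        loadings[block, j] = rng.uniform(0.5, 1.5, size=len(block))

    rate = activities @ loadings.T
    rate *= library_size_mean / rate.sum(axis=1).mean()
    if nb_dispersion > 0:
        # gamma-Poisson mixture: var = mu + dispersion * mu^2
        shape = 1.0 / nb_dispersion
        rate_noisy = rng.gamma(shape, rate / shape)
        counts = rng.poisson(rate_noisy)
    else:
        counts = rng.poisson(rate)

    factor_names = [f"F{j + 1}" for j in range(k)]
    n_ct = n_cell_types or k
    ct_names = [f"celltype_{i + 1}" for i in range(n_ct)]
    mixing = np.zeros((n_ct, k))
    for i in range(n_ct):
        mixing[i, i % k] = 1.0
    mixing += rng.uniform(0.0, 0.05, size=mixing.shape)
    densities = activities @ mixing.T + np.abs(rng.normal(0.0, 0.01, size=(len(grid), n_ct)))

    counts_df = pd.DataFrame(counts.astype(np.int64), index=grid.index,
                             columns=pd.Index(gene_ids, name="gene_id"))
    dens_df = pd.DataFrame(densities, index=grid.index, columns=ct_names)
    annotation = annotate_regions(grid, regions)
    truth = SyntheticTruth(
        factor_loadings_true=pd.DataFrame(loadings, index=gene_ids, columns=factor_names),
        factor_activities_true=pd.DataFrame(activities, index=grid.index, columns=factor_names),
        rate_matrix=pd.DataFrame(rate, index=grid.index, columns=gene_ids),
        regions=regions,
        density_mixing=pd.DataFrame(mixing, index=ct_names, columns=factor_names),
        seed=seed,
    )
    return grid, counts_df, dens_df, annotation, truth


def plant_border_labels(
    grid: pd.DataFrame,
    field: pd.DataFrame,
    bin_rates: dict,
    baseline_rate: float,
    seed: int,
    bin_width_um: float = 100.0,
    label: str = "planted",
    inside_key: str = "inside",
) -> pd.Series:
    """Label spots independently with probability
    ``baseline_rate × rate(bin)`` given a radial distance field.

    ``bin_rates`` maps exterior bin indices (and optionally ``inside_key``
    for spots inside the region) to rate multipliers; unlisted bins use a
    multiplier of 1. Returns a Series of ``label``/``None`` over the spots
    of ``field``.
    """
    rng = np.random.default_rng(seed)
    field = field.loc[field.index.intersection(grid.index)]
    d = field["d_um"].to_numpy(float)
    is_roi = field["is_roi"].to_numpy(bool)
    probs = np.empty(len(field))
    for i in range(len(field)):
        if is_roi[i]:
            rate = bin_rates.get(inside_key, 1.0)
        else:
            rate = bin_rates.get(int(np.floor(d[i] / bin_width_um)), 1.0)
        probs[i] = baseline_rate * rate
    if (probs > 1.0).any():
        raise ValueError("baseline_rate × bin rate exceeds 1 for some bin")
    hit = rng.random(len(field)) < probs
    out = pd.Series([label if h else None for h in hit], index=field.index,
                    dtype=object, name="cluster")
    return out


def simulate_density_blocks(
    n_spots: int = 600,
    n_blocks: int = 3,
    types_per_block: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cell-type density matrix with planted colocalization blocks.

    Spots are split into ``n_blocks`` equal zones; every cell type of
    block b is a per-type affine transform of that zone's indicator
    (``amp × 1[zone == b] + baseline``, amp and baseline drawn per type),
    so within-block correlations are exactly 1 and across-block
    correlations exactly −1/(n_blocks − 1) — the strongest mutual
    anticorrelation three or more exclusive compartments can have.
    Optional additive noise (``noise_sd``) perturbs the profiles; note
    that independent noise attenuates the across-block anticorrelation
    toward zero (clipping at 0 is applied and warned about).
    Returns (densities, true block label per cell type).
    """
    rng = np.random.default_rng(seed)
    zones = np.repeat(np.arange(n_blocks), int(np.ceil(n_spots / n_blocks)))[:n_spots]
    rng.shuffle(zones)
    cols, labels = {}, {}
    for b in range(n_blocks):
        indicator = (zones == b).astype(float)
        for t in range(types_per_block):
            name = f"type_b{b}_{t}"
            amp = rng.uniform(0.8, 1.2)
            baseline = rng.uniform(0.1, 0.3)
            vals = baseline + amp * indicator
            if noise_sd > 0:
                vals = vals + rng.normal(0.0, noise_sd, size=n_spots)
                n_clip = int((vals < 0).sum())
                if n_clip:
                    warnings.warn(f"{name}: clipped {n_clip} negative densities")
                vals = np.clip(vals, 0.0, None)
            cols[name] = vals
            labels[name] = b
    index = pd.Index([f"spot_{i:04d}" for i in range(n_spots)], name="spot_id")
    densities = pd.DataFrame(cols, index=index)
    return densities, pd.Series(labels, name="block")
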