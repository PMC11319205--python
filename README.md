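# fibroniche

Spatial niche analysis for Visium-style spot transcriptomics of fibrotic
lung tissue.

In idiopathic pulmonary fibrosis (IPF) and in the bleomycin mouse model,
the cellular neighborhoods that drive disease — fibroblastic foci, the
aberrant-basaloid (KRT5⁻/KRT17⁺) epithelium at their borders, Krt8⁺
transitional alveolar cells — are spatial objects: what matters is not
just which cell states exist but *where* they sit relative to annotated
histology. `fibroniche` implements the analysis workflow for asking such
questions of spot-resolution data (hexagonal capture-spot lattices at
~100 µm pitch, each spot a mixture of cells), end to end and fully
testable on synthetic sections with known ground truth.

## What it computes

* **Factor niches.** The spots × genes normalized matrix X is factorized
  by NMF, X ≈ W Hᵀ with W ≥ 0 the per-spot factor activities and H ≥ 0
  the gene weights. A factor's niche is its F^hi set — the spots in the
  top tail (99th percentile by default) of its activity — which can be
  subclustered (PCA → shared-nearest-neighbor graph → modularity
  communities) into cell-state-like populations.
* **Signed radial distance fields.** For a set of annotated region spots
  (e.g. fibroblastic foci), every spot gets a signed distance d in µm:
  the first exterior ring of spots sits at d = 0, each further ring adds
  one lattice pitch, and spots inside the region get d < 0. Distances
  are binned at 100 µm (one ring per bin) and capped at 3,000 µm.
* **Permutation-null border enrichment.** For a cluster label and
  distance bin d, the observed labeled-spot count x_d is compared to a
  null built by shuffling the full per-sample label multiset k = 100
  times:

  Z_d = (x_d − μ_d) / σ_d

  with μ_d, σ_d the mean and standard deviation of the count across
  shuffle rounds, and a two-sided p-value from |Z_d|. This is the test
  behind "is this spot population enriched at the focus border?".
* **Colocalization compartments.** Cell types (from external
  deconvolution densities) are clustered on the distance 1 − r between
  their spot-density vectors; cutting the dendrogram at height h = 1.5
  yields compartments, and per-spot compartment scores are the summed
  member densities.
* **Distance–expression correlation.** Pearson r of each gene (the 1,000
  most variable by default) against d within 500 µm of the region
  border, Benjamini–Hochberg corrected.
* **Pseudobulk DE and cross-species overlap.** Raw counts summed per
  donor/animal (optionally per annotated region), a simple
  Welch-t-on-log2-CPM differential test (external DESeq2-style tables
  can be injected instead), and overlap of significant genes across
  species through an ortholog map — including the sign-discordant subset.
* **Cross-species factor matching.** Jaccard index over top-100
  contributing gene sets for every factor pair; pairs above 0.1 are
  flagged as major overlaps.

A synthetic-data module generates hex lattices, planted circular regions,
factor-structured Poisson counts, linked cell-type densities and labels
with distance-dependent border enrichment, so every stage is exercised
against analytically known truth.

## Worked example

Simulate a 20×20 section with a 300 µm focus, plant labels at 5× the
baseline rate inside and at the border, and test for border enrichment:

```python
import fibroniche as fn

grid, counts, dens, ann, truth = fn.simulate_section(
    n_rows=20, n_cols=20, n_genes=100, k=3, seed=42,
    region_spec=[("fibroblastic foci/fibrous tissue", (950.0, 820.0), 300.0)],
)
roi = set(ann.index[ann == "fibroblastic foci/fibrous tissue"])
field = fn.radial_distance_field(grid, roi)
bins = fn.assign_distance_bins(field)
labels = fn.plant_border_labels(grid, field, {0: 5.0, "inside": 5.0}, 0.05, seed=3)
table = fn.border_enrichment_test(bins, labels, grid["sample_id"],
                                  fn.EnrichmentParams(k=100, seed=1))
print(table[table["bin"] <= 1][["cluster", "bin", "x", "mu", "sigma", "z", "p"]]
      .round(3).to_string(index=False))
```

prints

```
cluster  bin  x   mu  sigma      z     p
planted   -1  4 2.02  1.295  1.529 0.126
planted    0 10 3.25  1.660  4.067 0.000
planted    1  1 2.19  1.426 -0.834 0.404
```

Bin −1 is the inside of the focus, bin 0 its first exterior ring. The
ten observed border labels against a null mean of 3.25 give Z₀ ≈ 4.1
(p < 10⁻⁴): the planted border enrichment is detected, while the
unenriched 100–200 µm ring (bin 1) stays at the null.

The whole pipeline — simulation of a four-section case/control cohort,
QC, NMF, F^hi selection and subclustering, distance fields, enrichment,
distance correlation, compartments, factor matching and pseudobulk DE —
runs from one config:

```sh
fibroniche run --demo --seed 1 --out demo_run/
fibroniche report --run-dir demo_run/
```

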