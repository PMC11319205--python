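# Methods

This note documents the models and procedures `fibroniche` implements,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions that pin down edge
cases. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

Spots live on a hexagonal lattice (pitch ≈ 100 µm, spot diameter 55 µm —
the diameter is metadata; all geometry uses spot centers). Coordinates
are stored in µm with y increasing downward (image convention);
pixel-to-µm conversion uses a per-sample scale factor supplied by the
caller, with the 100 µm pitch as the natural sanity anchor. Barcodes are
opaque, case-sensitive strings. All containers are plain pandas objects
with documented schemas (`fibroniche.schemas`); cell-type densities are
consumed as produced by external deconvolution and never re-estimated.

## Quality filtering and normalization

Default thresholds follow the human preset — minimum 350 UMIs per spot,
100 UMIs per gene, 10 genes per spot, 5 spots per gene, and a 30% cap on
the combined mitochondrial/hemoglobin fraction — with a mouse preset
(300 UMIs per spot, no genes-per-spot minimum, lowercase gene prefixes).
Mito/hemo genes are matched by symbol prefix (`MT-`, `HBA`/`HBB`;
`mt-`, `Hba`/`Hbb` for mouse), overridable. The cap is applied to the
sum of the two family fractions by default (`fraction_mode="sum"`, the
most conservative reading of "more than 30% mitochondria and/or
hemoglobin"); a per-family mode is available.

Filter order within a round is fixed: (1) gene filters, (2) spot filters
computed on the gene-filtered matrix, (3) the mito/hemo fraction
computed on the matrix as it entered the round. Because spot removal
changes gene totals, a single pass is not a fixpoint; the round is
iterated until nothing changes, which makes the operation idempotent
(`filter(filter(X)) = filter(X)`) at the cost of occasionally removing
slightly more than one pass would. The QC report records per-round
removal counts. An optional gene→chromosome table removes X/Y genes; a
static biotype column is honored if present, never fetched.

Normalization is log1p of counts scaled to 10,000 per spot (log-CP10K).
This is a deliberate, documented stand-in for regularized-NB approaches:
every statistic downstream in scope (NMF, Pearson correlation) needs
only a variance-stabilized, depth-corrected, non-negative matrix.
Donor/batch regression is out of scope; runs over multiple samples log a
note to that effect.

## NMF factor model

X (spots × genes, normalized) ≈ W Hᵀ with W, H ≥ 0, minimizing the
Frobenius reconstruction error by classic multiplicative updates from a
deterministic NNDSVDa initialization (SVD-based, zeros filled with the
matrix mean). The optimizer was written in-package because downstream
contracts need three properties an off-the-shelf fit does not expose
together: a per-iteration objective trace (asserted non-increasing),
bit-level determinism for identical input, and the non-negativity
guarantee. A test cross-checks the final reconstruction error against an
independent optimizer of the same loss. Default K = 30 matches the
study design for real sections; synthetic tests use the planted K.
Iteration stops at `max_iter` (500) or when the relative objective
decrease falls below `tol` (1e−5). The NMF input is the normalized
matrix *without* z-scaling, which would break non-negativity.

**F^hi selection.** Percentile mode takes the linear-interpolation
(type-7) quantile of activity at q (default 99) over the chosen scope —
dataset-wide by default, per-sample optionally, since the original
convention is ambiguous — and keeps spots *strictly* above it. The
strict inequality means a constant-activity factor selects nothing
rather than everything. Top-n mode takes the n highest-activity spots
per scope unit, ties broken by spot id.

**Gene rankings.** Top-n genes per factor (n = 100 by default), ordered
by descending raw weight with ties broken by gene id; weights are
min–max scaled to [0, 1] over the selected n, with the degenerate
all-equal case defined as 1 (0 if all weights are zero).

**Summaries.** Per factor × group the package reports the F^hi
frequency |F^hi ∩ group| / |group|, the mean z-scaled activity
(centered/scaled over all scored spots), and a detection rate defined as
the percentage of group spots whose activity exceeds the factor's
dataset-wide mean — the original "percentage of spots with increased
activity" does not pin a threshold, so the dataset mean is used and
documented here.

**Subclustering.** PCA on centered features (default 8 PCs), a
shared-nearest-neighbor graph (k = 20 neighbors, Jaccard edge weights,
pruned below 1/15), and Louvain modularity communities at the given
resolution (default 0.4) with a fixed seed; clusters are relabeled by
size. Cluster *counts* on real data are outcomes, not contracts; tests
assert recovery of planted structure (ARI) instead.

## Spatial geometry

Adjacency links spots whose centers are within 1.2 × pitch (giving the
six hex neighbors), per sample only. The signed radial distance to a
region of interest (ROI) is Euclidean-with-offset: for exterior spots
d = max(0, distance to the nearest ROI spot center − pitch), so the
first exterior ring sits at exactly 0 µm and 100 µm bins correspond to
one ring each; ROI spots get d = −(distance to the nearest exterior spot
center), strictly negative. A hop-count mode (d = (hops − 1) × pitch) is
available for sensitivity checks. Singleton ROI components (size 1 under
lattice adjacency) are kept by default, matching the enrichment
convention, and can be dropped for distance-correlation analyses.

Binning is half-open, [i·w, (i+1)·w) at w = 100 µm; d equal to the
maximum distance (3,000 µm) is retained, larger distances are discarded;
ROI spots occupy a reserved inside bin (−1).

One discretization caveat: for a disk ROI made of lattice spots the bin
index is monotone in true center distance only up to one bin — the
discrete disk boundary is jagged, so two spots near a ring boundary can
swap order. For a point ROI the monotonicity is exact. The tests encode
exactly this.

## Border enrichment statistic

Given per-spot bins and cluster labels, the observed count x_d of each
(cluster, bin) is compared to a permutation null: the full per-sample
label multiset — labeled and unlabeled states alike — is shuffled
uniformly k = 100 times (the literal reading of shuffling "across all
spots within each sample"; restricting the shuffle to the selected spots
only is a documented alternative mode one could add, but the full-sample
multiset is what the package implements), counts are re-registered per
bin each round, and

Z_d = (x_d − μ_d) / σ_d,  σ_d with denominator k − 1.

p-values are two-sided from the standard normal by default; a Student-t
option with k − 1 degrees of freedom exists because the original
description ("two-tailed t-test" on Z-scores) is ambiguous — the choice
is recorded in the output parameters. σ_d = 0 rows are flagged and get
no Z rather than ±∞. With multiple samples the default pools counts
across samples round-by-round (so the null describes the pooled count);
per-sample tables are available instead.

The statistic is validated three ways: against exhaustive enumeration of
all label placements on a fixture small enough to enumerate (exact μ_d,
σ_d), for calibration under spatially random labels (|Z| > 1.96 in ≲5%
of bins, mean Z ≈ 0), and for power against labels planted at 5× the
baseline rate in the first border bin.

## Region neighborhoods and distance correlation

Region neighbors are all spots within a maximum number of graph hops
(default 2) of any ROI spot, excluding the ROI itself. Feature-vs-
distance correlation restricts to exterior spots with 0 ≤ d ≤ 500 µm
(optionally including the inside), keeps the n most variable features in
the window (plain variance of the normalized values; default 1,000),
computes Pearson r with the usual t-distributed p-value, excludes and
flags constant features, and applies Benjamini–Hochberg step-up over the
tested features.

## Colocalization compartments and factor matching

Compartments cut a hierarchical clustering of cell types at height
h = 1.5 on the distance 1 − r (range [0, 2]; 1 − |r| was rejected
because anticorrelated types must not co-compartmentalize). Linkage is
complete by default (average available); configured name patterns (e.g.
`NA`, `low.quality`) and constant columns are dropped before
correlation. The cut is *strict*: types merge into one compartment only
when their merge height is below h. The distinction matters only at
exact equality, which real data never hits but the theoretical optimum
for mutually exclusive blocks does: for any three variables the pairwise
correlations satisfy a + b + c ≥ −3/2, so three mutually exclusive
compartments can be pairwise anticorrelated at best at exactly −1/2 —
distance exactly 1.5. The strict cut keeps that best case separated.
Spot-wise compartment scores are the summed member densities, so scores
conserve each spot's total density over the partitioned types.

Cross-species factor matching maps the second ranking's genes through a
two-column ortholog table (one-to-many rows collapse deterministically
to the first pair after sorting, with a warning); unmapped genes stay in
the union but never the intersection. Jaccard = |A∩B| / |A∪B| per factor
pair; pairs above 0.1 are flagged as major overlaps.

## Pseudobulk and differential expression

Pseudobulk rows are exact integer sums of raw counts over all spots of a
donor/animal, optionally restricted first to a set of annotated region
labels (an empty selection is an error, not an empty matrix). The DE
test is a per-gene Welch t-test on log2(CPM + 1) across groups with
log2FC = log2((mean_case + 1)/(mean_control + 1)) on mean CPM and BH
correction — deliberately simple, because the claims the package tests
concern aggregation conservation, set logic and calibration, not
dispersion modeling; externally produced DE tables with the same schema
can be injected. Cross-species overlap restricts both tables to the
shared ortholog-mapped universe and reports significant sets (p_adj
below α, |log2FC| above a threshold, default 0), their intersection, and
the sign-discordant subset (significant on both sides, opposite
fold-change signs).

## Synthetic data: what it emulates and what it does not

`simulate_section` produces a hex lattice (even rows at x = col·pitch,
odd rows offset pitch/2, rows pitch·√3/2 apart), circular annotated
regions, K factor activity fields (Gaussian bumps anchored on regions or
on fixed well-separated background loci, over a 0.05 baseline),
block-structured gene loadings (uniform 0.5–1.5 within a factor's gene
block, zero outside — so the noiseless rate matrix has rank exactly K),
Poisson counts around the rate matrix scaled to a target library size
(negative-binomial dispersion optional, default 0), and cell-type
densities linked to the activities through a non-negative mixing matrix
plus noise. Identical seeds give bit-identical outputs.

`simulate_density_blocks` plants colocalization compartments as per-type
affine transforms of equal-zone indicators: within-block correlation
exactly 1, across-block exactly −1/(n_blocks − 1) — the strongest mutual
anticorrelation mutually exclusive compartments can have (see above).
Additive noise is available but documented to attenuate the
anticorrelation toward zero.

Not emulated: H&E images, sequencing-depth gradients, spot swapping or
transcript bleed, overdispersion beyond the optional NB parameter,
irregular region shapes (disks keep every geometric oracle analytic),
and donor-level batch structure. Passing tests therefore demonstrate
correctness of the statistics and geometry under the stated generative
model, not robustness to those real-data artifacts.

## Problem sizes and defaults used in checks

The packaged checks run on sections of 400–2,025 spots (20×20 to 45×45),
100–300 genes, K = 3–5 planted factors, library size 5,000, shuffle
counts k = 100–20,000, and a four-section demo cohort (two case with a
300 µm focus, two control) of 3,600 spots total at K = 5 — sizes chosen
so every oracle (brute-force geometry, exhaustive permutation null,
hand-counted set arithmetic) is computable exactly while the planted
signals remain comfortably detectable. The demo uses the 95th activity
percentile for F^hi (a 3,600-spot cohort leaves too few spots above the
99th for stable subclustering) and 50-gene Jaccard rankings; real-data
runs default to the study conventions (99th percentile, top-100 genes,
K = 30).

## Known limitations

* Log-CP10K is not a regularized-NB normalization; factor loadings on
  strongly overdispersed data will differ from SCTransform-based runs.
* The DE stand-in has no shrinkage; at 2–4 replicates its power is
  limited and its fold-change estimates are unmoderated.
* Euclidean-minus-pitch distance ignores tissue holes; the hop mode
  respects them but quantizes distance to the pitch.
* The permutation null conditions on the label multiset only; spatial
  autocorrelation of labels under the null is not modeled.
* One-to-many ortholog resolution (first listed pair) is a convention,
  not biology; supply a curated one-to-one map where it matters.
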