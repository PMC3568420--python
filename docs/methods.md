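# Methods

## Data model and scope

A study is a complete (no missing values) genes × samples matrix of
log2-scale intensities plus a per-sample annotation table of opaque
strings. Values are assumed already preprocessed and log-transformed
(fRMA-like); no transform is applied on read and missing values are
rejected rather than imputed, because every merging method below is
defined on complete log-scale matrices. Cross-platform merging keeps only
the genes common to all studies; the common set is sorted
lexicographically so the merged output is deterministic regardless of the
input row orders. Probe-set-to-gene collapsing is out of scope: inputs are
assumed to be gene-level already.

## Merging methods

**NONE / BMC / GENENORM.** Column concatenation; per-gene per-batch
mean-centering; per-gene per-batch z-scores (sample sd, denominator n−1).
GENENORM refuses single-sample batches (sd undefined); zero-variance genes
are centered only, logged, and listed in the output provenance.

**COMBAT.** The empirical-Bayes location/scale model
`y_gj = α_g + X β_g + γ_ig + δ_ig ε_gj`. Fitting: (1) per-gene OLS on the
batch-indicator design (plus optional single categorical covariate,
drop-first coded; a design in which a batch is fully determined by the
covariate is rejected as confounded); the grand location is the
sample-size-weighted combination of the batch coefficients and the pooled
variance is the mean squared residual over all N samples; (2) per-batch
means/variances of the standardized data give `γ̂_ig`, `δ̂²_ig`; priors are
parametric only — normal for γ across genes, inverse-gamma for δ² across
genes — fitted per batch by method of moments; (3) the EB fixed point
iterates γ*, δ²* until the maximum relative change drops below 1e-4
(at most 100 iterations; non-convergence flags the model but still returns
data); (4) back-transformation restores the pooled scale, grand location
and covariate effects. By construction γ* is a convex combination of γ̂
and the batch prior mean, and the shrinkage vanishes as the batch grows.
Zero δ̂² receives a 1e-8 floor before prior fitting. Note an
identifiability fact relevant when validating against simulations: the
grand location absorbs the weighted mean batch shift, so only each batch's
deviation from that weighted mean — not the raw per-batch shift — is
estimable.

**DWD.** For two batches, the separating direction solves
min Σ 1/margin_i + C Σ slack_i over unit directions. Eliminating the
slacks yields the standard convex DWD loss V(r) = 1/r for r ≥ 1/√C and
2√C − C·r below; the direction lies in the span of the samples, so the
problem is solved in that subspace with the unit constraint absorbed by
the parametrization w = q/‖q‖ (BFGS, gradient tolerance 1e-12). The
penalty defaults to C = 100 / (median inter-batch distance)², the
customary choice in the DWD literature; the contract is the post-condition
below, not a particular solver. The adjustment removes each batch's mean
displacement along w *relative to the grand mean*: x* = x − ((x̄_batch −
x̄)·w)·w. This preserves the overall location, leaves identical batches
untouched, and makes each batch's mean deviation from the grand mean
orthogonal to w (checked to 1e-8). Removing the absolute mean projection
instead would translate the whole data set along w (by roughly ‖x̄‖ on
all-positive log2 data) without changing any between-batch relation, which
is why the relative form was chosen.

**XPN.** Per repetition: genes are clustered into K groups and samples
(of both platforms jointly) into L groups by k-means on the row-
standardized combined matrix; within each platform the block-linear model
`x_gj = A_[k(g), l(j)]·b_g + c_g + σ_g ε` is fitted by alternating least
squares (weighted block means ↔ per-gene regression on the block
predictor, iterated to a 1e-9 fitted-value tolerance); platform-specific
`A, b, c, σ` are replaced by sample-size-weighted common estimates (block
means weighted by the samples each platform contributes to the sample
cluster, so a platform absent from some cluster simply contributes weight
0); each platform's data are reconstructed as common fit plus rescaled
standardized residual. Reconstructions are averaged over 30 repetitions
with fresh clusterings. Defaults K=25, L=5 shrink automatically on small
inputs (K ← min(25, ⌊genes/2⌋), L ← min(5, smallest batch));
explicitly requested counts exceeding the data are errors. One user seed
expands to per-repetition k-means seeds through a `SeedSequence` spawn, so
runs are bit-reproducible. When the two platforms carry identical data the
common estimates equal the per-platform ones and the reconstruction is the
identity, a property the tests exploit.

**Pairwise folding.** XPN and DWD are defined for exactly two studies.
More studies are merged by a left fold in the order supplied: the first
two are merged, the result is treated as a single batch at the next step
(its samples keep their original study labels in the `Study` annotation),
and so on. The user seed is used as-is for the first step and expanded by
a fixed counter scheme for later steps, so the two-study case coincides
with a direct call. The fold order is a reproducibility choice, not a
statistical one.

## Quantitative validation

*Genes overlap (GOV).* Per common gene, both studies' values are turned
into discrete densities on a shared 256-point grid spanning the pooled
range padded by three bandwidths, using a Gaussian kernel with the larger
of the two studies' Silverman bandwidths (sharing one bandwidth makes the
index symmetric; Silverman degenerates to a 1e-3 floor on constant data).
GOV_i is half the L1 distance between the two unit-mass vectors — the
discrete total-variation distance, the only reading consistent with the
[0,1] bounds and the identical/disjoint extremes — and GOV is the mean
over the m common genes. Sampling noise alone leaves a floor: two
independent n=50 draws of the *same* distribution give GOV ≈ 0.12, an
order of magnitude below typical batch-shifted values (≈ 0.75), so GOV is
read comparatively (before vs after), not against zero.

*Other indices.* Per-sample skewness uses the biased Fisher–Pearson g1
(no small-sample correction); constant samples are flagged and excluded
from the summary. Before/after correlations are Pearson, per sample and
per gene, zero-variance vectors flagged. The significant-genes overlap
ranks genes by |Welch t| on a two-level phenotype (ties broken by gene
ID) and counts known control genes in the top N; ranking only, no
multiple-testing correction, by design. The samples overlap is the mean
Euclidean distance of each sample to its nearest sample from another
batch. A caveat the indices make visible rather than hide: after
mean-centering methods (BMC, GENENORM) the per-sample before/after
correlation is *inherently* small, because centering removes the per-gene
baseline that dominates every sample's cross-gene profile; only
baseline-preserving methods (COMBAT, DWD, XPN) keep it high.

## Visual diagnostics

Coordinates are computed separately from rendering so tests are numeric.
MDS is classical (Torgerson) scaling of Euclidean inter-sample distances,
two components, exact for three points. RLE values are deviations from
each gene's across-sample median, summarized by Tukey box statistics.
The dendrogram uses complete linkage on Euclidean distances. RLE and
dendrogram displays subsample to 40 samples with an explicit seed.
Gene-wise densities reuse the Parzen estimator on a shared per-gene grid
padded by six bandwidths, so the truncated kernel tails keep the
trapezoid normalization error below 1e-6. In rendered figures, color
encodes the biological label and symbol/grouping the batch.

## Simulator

`simulate_studies` draws, per gene, a baseline α_g ~ N(7, 2²) log2 units
shared across studies; per study, an additive shift γ_gs ~ N(0,
additive_batch_sd²) (default sd 2, a deliberately strong batch effect of
the same order as the baseline spread) and a multiplicative factor δ_gs,
log-normal with log-sd 0.1; noise sd 0.5; the first 10% of genes (in
sorted order, for reproducibility) carry a +2 log2 case–control effect,
with balanced classes per study. This emulates the location/scale batch
model the EB adjustment assumes — which is exactly why it is a fair probe
of parameter recovery and a *favorable* scenario for COMBAT; it does not
emulate gene–gene correlation, probe-level artifacts, platform-specific
dynamic-range compression, or outlier samples, so passing tests show
correctness of the machinery, not field performance on arbitrary real
data. One global seed expands to a shared gene-level stream and per-study
streams via fixed offsets.

## Problem sizes and numerical choices

The default test scenario uses 500 genes and two studies of 50 samples —
small enough for the whole suite to run in well under a minute while
keeping every estimate (EB shrinkage, k-means blocks, KDE overlap) in its
asymptotically meaningful regime; parameter-recovery checks use 1000
genes. Tolerances: EB fixed point 1e-4 (relative), XPN inner fit 1e-9,
DWD gradient 1e-12, GOV/centering assertions at 1e-9–1e-6 as the
corresponding closed forms allow. TSV serialization uses 12 significant
digits, making write→read round-trips exact to < 1e-9.

## Known limitations

Exactly one categorical covariate is supported in COMBAT; covariate-rich
designs are out of scope. DWD and XPN assume two batches per step; the
left-fold extension is a pragmatic convention. GOV depends on the
bandwidth rule (values are comparable across methods within a run, not
across bandwidth conventions). No missing-value support, no
discretization-based merging, no repository access.
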