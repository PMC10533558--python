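# Methods

This note documents the models and procedures implemented in `thalamograd`,
the parameters that matter, the synthetic data the package is validated on,
and the numerical and design choices made where more than one reasonable
option existed.

## Matrix assembly

**Participant QC.** Each participant contributes a binary vector marking
which seeds fall inside their individually registered thalamic mask. A
participant is retained when the mean pairwise Pearson correlation of that
vector with all other participants' vectors is at least `threshold`
(default 0.7). The correlation of two {0,1} vectors is the phi coefficient;
a zero-variance vector (all seeds in or all out) has no defined correlation
and is excluded with the reason code `constant_vector`. Note a consequence
of the mean-over-others rule: a single strongly anticorrelated outlier also
drags down the mean of every participant it is compared against, so in tiny
cohorts the threshold can exclude more than the outlier.

**Seed QC.** A seed is retained when it is present in strictly more than
`presence_fraction` (default 0.85) of the retained participants *and* lies
where expression data exist. The inequality is strict: a seed present in
exactly 85% of participants is dropped.

**Expression assignment.** Seeds take the value of the voxel containing
them. World coordinates map to voxel indices through the inverse affine
followed by floor (half-open voxel convention); a seed exactly on a voxel's
upper boundary belongs to the lower voxel. A configurable sentinel (NaN by
default) marks voxels without data; seeds landing there get
`has_expression = False`.

**Averaging and normalisation.** Raw per-participant streamline-count
matrices are averaged arithmetically *before* normalisation; the
group-average matrix is the only one normalised. Each feature is then
passed through S(x) = 1/(1 + exp(−(x − mean)/sd)) with the sample standard
deviation (n − 1 denominator; both the mean and sd are recorded in
`SigmoidParams` for audit), and linearly rescaled to attain exactly 0 and
1. The sigmoid of the within-feature extrema is never exactly 0 or 1, so
the rescale step is mandatory. The transform is strictly increasing, hence
rank-preserving per feature, and compresses outliers relative to min–max
scaling — with the caveat that the compression is only visible when the
non-outlier values are not all identical (with exactly two distinct values
any [0,1] rescaling gives the same result). Constant features raise an
error by default; a config option passes them through as all-0.5, logged.

## Decomposition

The concatenated matrix is column-centred and factored by thin SVD; scores
are US, loadings V, and the variance explained by component k is
λ_k = s_k²/(n − 1), with fractions taken over the full spectrum so they sum
to one and Σλ equals the total variance of the centred matrix. Components
beyond the numerical rank are kept with λ ≈ 0 and a warning. Because SVD
signs are arbitrary, each component is oriented so its seed scores
correlate positively with the +x coordinate when coordinates are supplied
(the orientation in which the principal medial–lateral axis is positive
laterally), falling back to making the largest-|loading| feature positive.
Z-scoring of a decomposition standardises, per component, three blocks
independently — seed scores, cortical-region loadings, gene loadings — and
is idempotent and rank-preserving.

**Diffusion embedding** is the nonlinear alternative: cosine affinity
between seed rows, anisotropic normalisation with α = 0.5, symmetric
eigendecomposition of the diffusion operator, and embedding coordinates
scaled by λ/(1 − λ) (diffusion time 0). α and the time are declared
defaults, not inferred; sparsification is off. A disconnected affinity
graph is an error reporting the component sizes. The five sensitivity
variants are: joint PCA on a restricted gene subset; per-modality PCA; PCA
on the 20-column concatenation of the two modalities' top-10 scores (the
columns are standardised first so neither modality dominates by scale);
diffusion embedding of the joint matrix; and diffusion embedding on the
mean of the two modality cosine-affinity matrices.

**Stability.** The participant bootstrap resamples connectivity matrices
with replacement, re-averages, re-normalises, re-decomposes, and records
per-replicate variance fractions and the |r| of replicate PC1 scores and
loadings against the original (the fixed gene block, which has no
participant dimension, is reattached unchanged). Leave-one-seed-out
cross-validation decomposes each (n−1)-row matrix and reports the RMSE of
the remaining seeds' PC1 scores against the original — after sign
alignment (sign chosen by correlation with the original) and z-scoring of
both vectors, since PCA components carry arbitrary sign and scale.

## Spatial nulls

**Spin test** (parcel maps on a sphere). A rotation drawn uniformly from
SO(3) is applied to the parcel centroids; rotated regions are then greedily
assigned: the rotated region with the minimal mean distance to all
remaining original regions is mapped to the remaining original region most
distant from it, both are removed, and the loop repeats until the map is a
bijection (ties broken by lowest index). Although the "most distant" step
looks anti-spatial, antipodes of neighbouring points are neighbours, so the
composed map is approximately an isometry and spatial contiguity is
preserved; empirically the test's type-I error sits at ~0.05 on smooth
Gaussian-process maps where the naive parametric test rejects at 0.3–0.5.
The default ensemble size is 10,000 permutations.

**Variogram surrogates** (volumetric seed maps). Per surrogate the base
values are randomly permuted; the permuted field is smoothed over k nearest
neighbours (Gaussian kernel, bandwidth = distance to the k-th neighbour)
for several candidate k (5–50% of n); for each candidate the binned
empirical variogram (25 equal-width distance bins up to the 70th percentile
of pairwise distances; empty bins on lattice geometries are dropped so they
cannot bias the fit) is affinely regressed onto the base map's variogram,
and the best candidate becomes √α·smoothed + √β·white-noise, recentred to
the base mean. The per-surrogate squared deviation between the fitted and
empirical variograms is emitted as a quality metric. An optional "resample"
mode rank-remaps each surrogate to the original value multiset (off by
default). Default ensemble size 1,000. The white-noise nugget makes the
test mildly conservative on very smooth maps.

**p-values.** Two-tailed on |r|, with the estimator
(#{|r_null| ≥ |r_emp|} + 1)/(n_perm + 1), which cannot return zero. When
both maps have an ensemble, each direction's p is computed and the mean
reported, making the test symmetric in the two maps.

## Axis genes, enrichment, cross-species

Axis genes are selected by correlating every gene with a component's seed
scores and comparing each correlation to the distribution of correlations
between that gene and variogram surrogates of the score map; among genes
with p_spin < 0.05, the 100 strongest positive and 100 strongest negative
by |r| are kept (ties broken by gene id; constant genes are excluded with a
reason; fewer are returned, with a warning, when significance thins the
pool). Selection is exactly antisymmetric under a sign flip of the
component.

Enrichment uses the upper-tail hypergeometric probability P(X ≥ x) — note
this is the survival function at x − 1, i.e. "x or more" — with fold
enrichment (x/n)/(K/N) and BH-FDR within one family per axis direction.
All sizes are computed after intersecting every set with an explicit
background universe; the background differs per analysis (all panel genes
for cell classes, all neuron-expressed genes for subclusters) and is always
a parameter. The signed medial–lateral ratio is +ratio for the
positive-axis (lateral) list and −ratio for the negative-axis (medial)
list; subclusters are ordered by the summed signed ratio. Optional minimum
and maximum set-size filters (defaults 4 and 2000 where used) support
disease-table analyses.

Cross-species comparison retains homologue pairs that appear in the
homology table, are on the protein-expression list, and exceed the
aggregated-expression cutoff: "top 75%" is implemented as strictly above
the largest value whose empirical CDF is ≤ 25% (the ⌊0.25 n⌋-th smallest),
so of 10 genes the 8 highest are kept; the boundary value is reported.
One-to-many homologies collapse to the partner with the highest aggregated
expression, ties by id, making the filter order-independent. Loading
correlations and nucleus-score-vs-hierarchy correlations are plain Pearson
with analytic Fisher-z intervals (nucleus-level data are too few and too
coarse for a spatial null).

## Developmental trajectories

The window classifier runs all pairwise Welch two-sample t-tests across the
nine developmental windows (windows with fewer than two samples are
dropped), BH-corrects within each gene's 36 pairs, counts significant pairs
that link a prenatal to a postnatal window, and labels a gene
prenatal-enriched (resp. postnatal) when at least three such pairs favour
that side and strictly more than favour the other. Welch+BH is a documented
choice — robust to unequal window variances — and swappable. Prenatal ages
are encoded as negative years from birth; window boundaries are an input
(the generator uses −0.75, −0.5, −0.25, 0, 1, 6, 12, 20, 40, 80 years).

Trajectories are mixed-effects models (statsmodels `MixedLM`): a natural
cubic spline in age with four knots evenly spaced over the observed span
(basis coded directly from the textbook truncated-cubic construction),
sex and RIN as fixed effects, and a per-donor random intercept — per donor,
not per sample, because a per-sample intercept with one observation per
sample is unidentifiable. Variance components use REML for the reported
coefficients; AIC/BIC comparisons between the spline and a linear-age null
use maximum-likelihood refits. Degenerate covariates (single sex, constant
RIN) are dropped with a warning; a zero random-intercept variance falls
back to zero donor offsets. Age-corrected relative expression removes the
sex/RIN effects and donor intercepts, leaving the age trajectory plus
residual noise. The population curve evaluator predicts at reference
covariates (balanced sex, mean RIN, zero random effect).

## The synthetic data

The generator's defaults are the package's reference study conditions: 500
seeds drawn from a 1.75 mm lattice inside an ellipsoid (semi-axes 20 ×
12.7 × 9.1 mm, sized so the full lattice holds ≈1800 points, the scale of a
bilateral thalamic mask); a planted gradient g = standardised x-coordinate
with orthogonalised y/z secondaries; 400 genes of which 80 (40 positive, 40
negative) equal ±g plus spatially autocorrelated Gaussian noise (sd 0.5,
exponential covariance, 5 mm length scale) while the rest are pure
unit-variance autocorrelated fields; connectivity W_ij = 100·exp(−(g_i −
a_j)²/(2·0.5²)) for a cortical axis a evenly spaced over the range of g,
plus per-participant Gaussian noise (sd 30) truncated at zero so counts
stay nonnegative; 20 participants; inclusion vectors sharing a base pattern
in which the 15% most peripheral seeds are excluded, flipped independently
at 3% per participant (the rate at which typical participants clear the
0.7 QC threshold while a 50%-flips corrupted participant fails it); marker
sets of 50 genes drawing 60% of their members from one planted set against
a 10% background rate; 120 developmental samples (20 donors × 6) with cubic
age trajectories (prenatal-declining, postnatal-rising, flat), a 0.6 sex
offset, 0.3 RIN slope, donor sd 0.4, noise sd 0.5; and a second-species
loading table equal to the planted loading pattern plus noise (sd 0.3),
linked by a one-to-one homologue map with gamma-distributed expression
aggregates. Everything is drawn from one `numpy` Generator in fixed order,
so a seed reproduces the dataset exactly.

What the generator does *not* emulate: tractography biases (distance
dependence, gyral bias, false-positive bundles), the covariance structure
of real microarray probes or donor effects in the expression maps,
hemispheric asymmetry, nucleus boundaries (the planted gradient is purely
linear in x), or realistic cortical geometry (parcels sit on a Fibonacci
sphere). Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the planted model; they do not certify the
anatomical conclusions that real data would support.

## Reference experiments and problem sizes

The benchmark experiments (shared by the acceptance tests and
`scripts/acceptance.py`) use these sizes, chosen as the package's reference
conditions: gradient recovery and selection precision on the default
dataset (500 seeds); PCA-vs-eigendecomposition agreement on 50 random
matrices up to 11 × 8; exhaustive hypergeometric enumeration for all
backgrounds N ≤ 12; null calibration with 300 spin pairs (100 parcels,
GP length scale 80 mm, 500 spins) and 200 variogram pairs (150 seeds,
length scale 15 mm, 500 surrogates per map); enrichment power over 100
marker-set replicates; trajectory recovery over 200 effect genes with 100
flat nulls; and variant concordance on a half-noise dataset. The spin
test's intrinsic mild anticonservatism (~0.055–0.065 true rate at these
settings) and the variogram test's mild conservatism (~0.035) both sit
inside the exact 95% binomial acceptance band at these replicate counts.

## Known limitations

* The variogram surrogate's additive white-noise nugget over-disperses
  surrogates of very smooth maps, making gene-axis p-values slightly
  conservative there.
* The topographic connectivity kernel's bump-shaped columns are
  non-monotone in g, so even noiseless pipelines recover g at |r| ≈ 0.98,
  not 1 (a mild horseshoe effect inherent to PCA on translation kernels).
* `MixedLM` occasionally warns on degenerate fits (zero residual or
  random-effect variance); fits remain usable and the warnings are
  suppressed inside the fitting routine only.
* The pipeline orchestrates the synthetic source end to end; analyses of
  real tabular/NIfTI inputs use the library functions directly.
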