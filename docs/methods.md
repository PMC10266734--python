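# Methods

`pharmaconet` implements a pipeline for relating drug-induced changes in
fMRI functional connectivity to the cortical distribution of
neurotransmitter receptors and transporters, together with a synthetic-data
generator that plants known structure in every quantity the pipeline
estimates. This note documents the models, the defaults and why they were
chosen, what the generator does and does not emulate, and the numerical
choices that matter.

## Pipeline model

**Delta maps.** For one subject scanned at baseline and under a drug, the
regional BOLD matrices (regions × time) are correlated pairwise (Pearson)
into FC matrices; negative edges are set to zero and each region's
*positive weighted degree* is the sum of its remaining off-diagonal edges.
The subject's delta map is degree(drug) − degree(baseline); a dataset's
contrast map is the across-subject mean. Clipping negatives to zero is
equivalent, for degree sums, to deleting negative edges. Regions with zero
temporal variance raise an error rather than propagating undefined
correlations.

**Co-susceptibility.** Entry (i, j) is the Pearson correlation between
region i's and region j's response profiles across perturbations
(concatenated subject-wise drug deltas, receptor densities, or disorder
effect-size maps). Matrices are compared edgewise by Spearman correlation
over the n(n−1)/2 strictly-upper-triangular entries (4,950 for 100
regions, 2,278 for 68). Because edge weights decay with distance, an
exponential trend `a·exp(−d/b) + c` can be fitted to the edges by
nonlinear least squares (multi-start over b ∈ {10, 40, 100} mm, free
offset) and removed from both matrices first; a confound similarity matrix
(the outer product z zᵀ of a z-scored non-gray-matter probability vector)
can additionally be regressed out edgewise by OLS. The free offset is this
package's choice — it absorbs the global edge mean so residuals are
centered; detrending on ranks is not offered.

**PLS correlation.** With X (regions × receptors) and Y (regions × drugs)
column z-scored (sample SD, n−1), one SVD of the cross-product XᵀY = USVᵀ
yields latent variables: U rows index receptors, V rows index drugs,
covariance explained per component is sᵢ²/Σsⱼ². Scores are projections of
the z-scored data onto U and V; loadings are Pearson correlations of each
original variable with the *receptor* score pattern of the component (the
same reference pattern for receptor and drug variables, so both loading
sets are comparable). Sign indeterminacy is resolved by forcing the
largest-|value| element of each U column positive. Loading CIs are
percentile bootstraps over regions (default 1000 resamples, seeded);
resampling units other than regions are not offered. This is symmetric
(correlation-flavored) PLS — a single decomposition, no deflation or
regression variant.

**Spin test.** Parcel centroids are centered per hemisphere and projected
onto the unit sphere. Per spin, one uniform random rotation (QR of a
Gaussian 3×3 with sign correction, det +1) is applied to the left
hemisphere and its x-mirrored version to the right; each original parcel
inherits the value of the nearest rotated parcel of its own hemisphere
(greatest dot product; ties to the lowest index). The reassignment may be
non-bijective, as the nearest-parcel rule allows. For PLS, the null
decomposes X against spun Y and the p-value per component rank is the
plain proportion of null singular values exceeding the observed one; a
conservative (k+1)/(n+1) mode is available and is never smaller.
Correlation-type spin tests are two-sided on |ρ|; singular-value tests are
one-sided (greater).

**Condition-permutation null.** Each permutation swaps, independently per
subject with a fair coin, the drug/baseline labels before recomputing
subject deltas, dataset means, and the PLS singular values. Because a
subject's delta map is exactly antisymmetric under the swap, the
implementation computes each subject's delta once and flips its sign —
identical results at a fraction of the cost. A null in which every
permuted contrast map is identically zero (e.g. identical scans in both
conditions) raises a degenerate-null error.

**Distance-dependent cross-validation.** Per split, the training set is
the 75% of regions nearest (centroid Euclidean distance) to a random
source region, the test set the distant remainder. PLS is fitted on
training rows; held-out rows, standardized with *training* means and SDs,
are projected onto the trained singular vectors, and the Pearson
correlation of held-out component-1 receptor vs drug scores is recorded.
The null permutes the held-out drug scores within splits (1000 times by
default); the p-value is the proportion of null mean correlations at least
as large. Default 100 splits. Note a known limitation of the method
itself: with strongly autocorrelated but independent maps the observed
statistic retains a small positive bias that the within-split permutation
null does not model, so the test is anticonservative in that regime; the
package's null-calibration guarantees are therefore stated for the spin
and condition-permutation tests.

**Gradients.** Similarity networks over the same parcellation are fused by
horizontal concatenation of rows followed by row-wise normalized-angle
affinity, 1 − arccos(cos)/π ∈ [0, 1] (cosines clamped to [−1, 1]; in dense
mode affinities below 0.5 are kept). Optional row-wise sparsification
retains the strongest 10% of entries per row before symmetrization by
transpose-averaging — the field-standard default for this embedding;
strongly modular synthetic networks can disconnect under it, in which case
the dense mode or the explicit `allow_disconnected` override applies. The
diffusion map uses the anisotropic normalization W̃ = D^−α W D^−α with
α = 0.5 (retaining global relations), row-normalizes to a transition
operator, eigendecomposes via the symmetric conjugate, discards the
constant stationary eigenvector, and scales component i by λᵢ/(1−λᵢ)
(diffusion time t = 0). The leading eigenspace is explicitly anchored to
the analytic stationary vector √deg so that, under degeneracy
(disconnected graphs), the retained components are signed contrasts rather
than arbitrary rotations of component indicators. Variance fractions are
normalized over the *retained* eigenvalues. Components carry the same
deterministic sign convention as PLS.

**Dominance analysis.** All 2ᵖ − 1 OLS submodels are fitted (p capped at
15); total dominance of predictor j averages its incremental R² first
within each submodel size (the empty model counts as size 0) and then
across sizes. This Shapley weighting is the default because it makes the
dominances sum *exactly* to the full-model R², which a flat average over
all submodels (also provided, `flat_average=True`) does not in general.
The exact-sum identity holds for plain R², not adjusted R²; both are
reported.

## Synthetic data: what it emulates

All generators are pure functions of (parameters, seed); a master seed is
split into independent per-purpose streams via `numpy.SeedSequence`.

- **Geometry**: n/2 parcels per hemisphere on a 70 mm sphere via a
  Fibonacci lattice (seeded rotation about x), mirrored across x = 0. For
  n = 100 the typical parcel spacing is ~25 mm.
- **Regional maps**: zero-mean Gaussian process draws with exponential
  covariance σ²·exp(−d/ℓ) over centroid distances (jitter 1e−8 σ² for
  positive definiteness). The exponential kernel matches the exponential
  distance trend the co-susceptibility stage removes. Default ℓ = 30 mm
  gives neighbor-parcel correlations ≈ 0.4, comparable to parcellated
  cortical maps; ℓ ≲ 10 mm is effectively white at parcel resolution and
  ℓ ≳ 5000 mm effectively constant (note the exponential kernel needs
  lengthscales far beyond the 140 mm maximal distance to look constant).
- **Receptor panel**: independent smooth maps, shifted non-negative (PET
  densities are non-negative). Real receptor maps are cross-correlated;
  independence here is deliberate so that recovery tests are not
  confounded by panel collinearity.
- **Drug panel**: Y = zscore(X)·W·C + E with W (receptors × k) and
  C (k × drugs) drawn once per seed and smooth GP noise E scaled per
  column to signal-variance/noise-variance = snr (default 4). The planted
  truth records W's first column and the latent regional pattern
  zscore(X)·W[:, 0]. Because the noise shares the maps' autocorrelation,
  recovery at fixed snr degrades with smoothness (fewer effective spatial
  degrees of freedom): at ℓ = 30 mm the 20-seed mean |cosine| between the
  PLS1 weights and the planted weights is ≈ 0.85–0.87.
- **Subject scans**: baseline covariance Σ₀ = BBᵀ + I from a random
  10-factor model (5% per-subject loading jitter so subjects are not
  copies); the drug condition scales row/column i by
  √(1 + gain·tanh(δᵢ/sd(δ))) (clipped to keep factors in (0.5, 1.5)),
  restores Σ₀'s diagonal so the perturbation acts on correlations, repairs
  to the nearest PSD matrix if needed, and samples both conditions as
  stationary Gaussian series. The expected effect on positive-edge
  weighted degree is monotone in the planted delta. No hemodynamics,
  autocorrelated noise, or motion artifacts are simulated, so passing
  tests demonstrate the estimator and null machinery, not robustness to
  fMRI confounds.
- **Disorder maps**: coupling·(random mixture of the drug contrast maps)
  + (1 − coupling)·independent smooth maps, column z-scored to emulate
  Cohen's-d effect-size maps. Mixtures use the *observed* (noisy) drug
  panel: with a single planted latent the noiseless panel is exactly
  rank 1 and its co-susceptibility degenerates to ±1 blocks.

## Default problem sizes

The acceptance script and the analysis drivers use a 100-region
parcellation, 19 receptor maps, 15 drug contrasts, 11 disorder maps,
15 subjects × 250 time points for scan-backed datasets, snr = 4, 200-spin /
200-permutation nulls for calibration sweeps (200 and 100 simulated
datasets respectively) and 1000-repetition nulls in the single-study
drivers. These mirror the motivating study's panel dimensions while
keeping each driver in the tens of seconds on one CPU.

## Numerical choices

- Exact symmetry of every similarity matrix is enforced by
  transpose-averaging on construction (inputs asymmetric beyond 1e−8 are
  rejected).
- Tables are written as TSV with `%.17g` floats — round-trips are exact.
- The exponential detrend fit uses tight optimizer tolerances (1e−14) so
  the free-offset least-squares property (zero residual mean) holds to
  1e−8.
- Eigen-solvers are dense symmetric (`eigh`) — appropriate at parcel scale
  (n ≤ 1000); no sparse/iterative path is provided.
- Ties in nearest-parcel reassignment and in the distance-CV region
  ordering are broken by the lowest region index (stable sorts).
- The p-value convention is the plain null proportion; the conservative
  (k+1)/(n+1) variant is available everywhere a null is resampled.

## Known limitations

- The synthetic generator's subject heterogeneity (5% loading jitter) and
  noise model are package choices; real pharmacological fMRI has richer
  between-subject and between-site variance.
- The spin test operates at parcel resolution only (no vertex-level
  rotation), and no variogram-matched surrogate alternative is provided.
- Distance-dependent CV anticonservatism under pure spatial
  autocorrelation, noted above.
- No volumetric or surface neuroimaging formats: the pipeline starts at
  parcellated plain-text tables.
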