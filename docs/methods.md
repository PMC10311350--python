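# Methods

This note documents the models and estimators implemented in `spatprot`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should know
about. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A dataset is a set of per-sample **cell tables** (cell id, centroid x/y in
pixels with x = column, y = row and origin at the top-left of the image,
optional cell-type label, and an expression vector over a fixed, ordered
biomarker panel) plus one **clinical table** mapping samples to patients
and coverslips (staining/imaging batches) and carrying a right-censored
outcome per patient: observed time T > 0 and event indicator δ, with δ = 0
meaning the patient was alive at T. All samples of a patient share (T, δ).
Cell tables are comma-separated UTF-8 with a header (a tab-separated
dialect is auto-detected); floats are written with 12 significant digits so
read/write round-trips are value-exact at that precision.

## Expression normalization and cell typing

Expression is z-scored per biomarker using the population (divide-by-n)
standard deviation, the convention used by single-cell scaling routines.
The default scope pools all cells of the dataset, since typing is trained
on cells pooled across samples; per-sample scope is available for
sensitivity analysis. Zero-variance biomarkers are mapped to 0 with a
warning rather than an error, so a blank channel does not abort a run.

Cell typing support follows the usual recipe: PCA to 20 components, a
k-nearest-neighbor graph (k = 30, Euclidean distance in PC space), and
modularity-based community detection (Louvain, resolution 1.0, seeded and
deterministic). Labels are transferred to remaining cells by k-NN majority
vote in the normalized expression space; vote ties go to the class whose
voting neighbors have the smallest distance sum. A caveat inherent to
modularity optimization: on a homogeneous point cloud it still partitions
the k-NN graph into several communities of comparable size (the resolution
limit), so "no structure" does not come out as "one cluster" at resolution
1.0. The resolution parameter is exposed; very low values merge a
homogeneous cloud into one community, which the tests exercise.

## Imaging quantities

Channel means over the full image and within the union of segmentation
masks give the two standard non-spatial intensity featurizations; per-cell
expression is the mean channel intensity over the cell's mask pixels, and
the centroid is the mean of its pixel coordinates. Positivity thresholds
for the threshold-based comparison features are the mean background
intensity per biomarker, pooled over all samples (background = pixels with
mask label 0); the accumulator is an associative merge of per-sample sums
and counts, so the threshold is invariant to how pixels are partitioned
into samples.

Whole-cell masks are approximated from nuclear masks by stochastic
dilation: per cycle, each background pixel flips to foreground with
probability equal to the fraction of positive pixels among its 8-connected
in-image neighbors (border pixels use only in-image neighbors in the
denominator), updated synchronously from the pre-cycle state; nine cycles
is the default. Dilation operates on the binary union of nuclei; labels
are then propagated to the grown region from the nearest nucleus pixel via
the exact Euclidean distance transform. Exact distance ties between two
nuclei are resolved by the distance transform's fixed scan order, which is
deterministic but not guaranteed to prefer the smaller label.

## Spatial statistics

The K-function of a stationary point process X with intensity λ is defined
by λK(r) = expected number of further points within distance r of a typical
point; under complete spatial randomness (CSR) K(r) = πr². The estimator is

    K̂(r) = A / (n(n−1)) · Σᵢ Σ_{j≠i} 1(dᵢⱼ ≤ r) · eᵢⱼ ,

summed over ordered pairs, with ties dᵢⱼ = r included. The isotropic
edge-correction weight eᵢⱼ is the reciprocal of the fraction of the circle
centered at point i with radius dᵢⱼ that lies inside the window. For
rectangular windows this fraction has a closed form: the exterior angle is
the union of the four per-edge arcs (half-angle arccos(dₑ/r) for an edge at
distance dₑ < r), with adjacent-edge overlaps removed by
inclusion–exclusion, max(0, α + β − π/2) per corner. Opposite-edge arcs
cannot overlap for an interior point and triple overlaps have measure zero,
so the formula is exact for every interior point and radius. The result is
clipped to [0, 1] against floating-point rounding; a pair whose circle
fraction falls below 10⁻⁶ raises rather than contributing an unbounded
weight. Besag's transform L̂(r) = √(K̂(r)/π) is the variance-stabilized
version (L(r) = r under CSR).

The mark-weighted estimator multiplies each pair term by
w<sub>ij</sub> = mᵢmⱼ/m̄² where m̄ is the pattern's mean mark. The
normalization makes constant marks reduce exactly to K̂, so the feature

    L̂ʷ'ᵐ_norm(r) = L̂ʷ'ᵐ(r) − L̂(r)

is identically zero for constant marks, positive where large marks
co-locate beyond the co-location of the points, and negative where marks
anti-correlate with local density. Marks must be non-negative: z-scored
expression is shifted per sample to minimum 0 before weighting (constant
columns short-circuit to an exact 0 feature), because negative pair weights
make the weighted sum non-monotone and uninterpretable as clustering.

Defaults: the window is the tight bounding box of the points (expandable by
passing an explicit `Window`); the r-grid is {0, 1, …, 400} px; feature
radii are 80 and 212 px, ≈30 and 80 µm at 0.375 µm/px — about the diameter
of 2–3 and 6–8 cells. Feature extraction evaluates the estimate only at
grid radii (no interpolation) and shares the pairwise distance/weight
computation across all biomarkers of a sample, which dominates the cost.

## Featurizations

* **Neighborhood matrix** (spatial): k = 10 nearest neighbors per cell by
  centroid distance, self excluded, exact distance ties broken by cell
  order for determinism. Rows of types present in the sample sum to 1;
  rows of absent types are flagged missing and imputed with 0 at assembly
  (an absent type has no observed interactions).
* **Spatial marker features** (spatial): L̂ʷ'ᵐ_norm at the two feature
  radii per biomarker, biomarker-major ordering — 2B values (78 for a
  39-plex panel).
* **Cell-type proportions**, **channel means** (non-spatial baselines).
* **Positivity fractions** and **neighbor interactions** (threshold-based
  comparison set): a cell is positive for a biomarker when its mean
  expression exceeds the pooled background threshold; the interaction
  feature for an ordered pair (a, b) is the mean, over cells positive for
  a, of the fraction of their k nearest neighbors positive for b —
  directional, on the same k-NN graph as the neighborhood matrix. The
  definition is exposed behind the function boundary so alternatives can
  be added.
* **Expression-density clustering** (comparison set): per biomarker, a
  Gaussian KDE (Silverman bandwidth) of each sample's cell-level
  expression on a common 512-point grid spanning the pooled range with 5%
  padding; pairwise Jensen–Shannon distances (base 2, hence bounded by 1)
  between renormalized discrete densities; average-linkage hierarchical
  clustering cut at 2; the cluster with the larger median expression is
  coded 1, which removes label-swap ambiguity. Degenerate constant samples
  become a point mass on the nearest grid point.

## Survival analysis

Harrell's C counts a pair (i, j) as comparable when the shorter time is an
observed event and the times differ; equal-time pairs are excluded and risk
ties receive half credit. It is implemented directly (the exact tie rules
are part of the contract) and checked against exhaustive pair enumeration.

The risk model is a random survival forest: default 1000 trees, log-rank
splitting, √p candidate features per split, minimum leaf size 3, seeded.
Sample rows inherit their patient's outcome for fitting; predicted risks
are averaged per patient when patient-level quantities are needed. Two
grouped cross-validation schemes prevent leakage: patient-grouped k-fold
(default 10 folds, patients never span folds) and leave-one-coverslip-out
(one fold per batch). Cross-validation redraws folds and forest seeds per
repeat and reports the distribution of fold-averaged held-out C with a
normal-approximation 95% CI over repeats. Held-out concordance is computed
at sample level (matching the training granularity); a patient-level
option averages risks first. Permutation importance is the mean drop in C
over n = 100 permutations of one feature column; constant columns are
exactly 0 by construction.

Stratification searches candidate thresholds (midpoints between
consecutive sorted unique patient risks, each cohort keeping at least
max(2, ⌈10% n⌉) patients) for the maximum log-rank statistic. The log-rank
statistic is computed directly from the hypergeometric sums (the
implementation is cross-checked against lifelines to machine precision in
the tests; the asymptotic χ²(1) p-value is used). Every stratification
result carries a mandatory caveat that the p-value is selection-biased:
it is computed at the maximizing cutpoint and not adjusted for the search.
Kaplan–Meier curves come from lifelines; cohort enrichment uses two-sided
Mann–Whitney U tests (SciPy) with Bonferroni correction.

## Synthetic cohorts

The generator emulates the structure of a segmented multiplexed-imaging
cohort at desk scale: by default 20 patients × 2 samples on 4 coverslips
(round-robin), ~300 cells per sample (Poisson) in a 1000 × 1000 px window,
8 biomarkers, 4 cell types, 30% censoring — roughly two orders of magnitude
below a real cohort (hundreds of samples, ~7000 cells each) so the full
test suite runs in minutes. Components:

* **Point processes**: CSR (uniform Poisson), Thomas clustering (Poisson
  parents, Gaussian-displaced Poisson offspring, rejection-clipped to the
  window), and hardcore inhibition (dart throwing; packing failure raises
  after a bounded number of attempts).
* **Marks**: i.i.d. lognormal; cluster-elevated (baseline × fold within
  one displacement sd of a parent; fold 1 reduces to i.i.d.); and
  distance-decay (nearest-neighbor distance rescaled to mean 1, a mark
  anti-correlated with density).
* **Cell types**: i.i.d. multinomial at mixing 1; below 1, cells inherit
  the label of the nearest of 8 seeded regions with probability
  1 − mixing, producing spatially segregated layouts whose neighborhood
  matrices depart from the composition.
* **Expression**: lognormal baseline with each type's signature biomarker
  elevated 3-fold, so expression encodes type identity for the typing
  tests.
* **Survival**: exponential event times with hazard
  λ₀·exp(β·(x − x̄)) per patient, where the β-named features (e.g. a
  neighborhood-matrix entry) are computed from the generated samples and
  averaged per patient; censoring times are uniform(0, τ) with τ solved
  numerically (Brent) so the expected censoring fraction equals the target.
* **Images**: cells rendered as disks into a labeled mask (later cell wins
  overlaps), channel intensity = expression inside cells and a low
  constant background, optional Gaussian noise truncated at 0. With zero
  noise, per-cell quantification of the rendering recovers the expression
  exactly.

What the generator does not emulate: microscopy point-spread functions,
autofluorescence and spectral bleed-through, batch effects between
coverslips, segmentation errors, cell-shape variation, or correlated
biomarker programs. Passing tests therefore demonstrate the correctness and
calibration of the estimators and the recoverability of planted effects —
not robustness to the artifacts of real CODEX data.

## Validation scenario choices

Two validation scenarios deserve explanation because their conditions were
design decisions:

* **End-to-end recovery** plants a hazard (β = 6) on the T0–T0
  neighborhood entry by drawing each patient's spatial mixing level
  uniformly on (0, 1); at 150 patients × 1 sample × 250 cells this yields
  cross-validated C around 0.7–0.8 and puts the planted entry at or near
  the top of the permutation-importance ranking. Neighborhood diagonal
  entries co-vary with the latent mixing level, so "top 3" rather than
  "top 1" is the meaningful criterion. Cross-validation in this scenario
  uses 150-tree forests — the statistic stabilizes well below the
  1000-tree default — and the null check draws features independent of
  outcome on fresh cohorts, since a chance-coverage CI must include
  cohort-level noise, not just fold-assignment noise.
* **Risk stratification** uses two latent groups (gap of 10 within-group
  sds in risk) with Weibull shape-3 event times at a 10× scale ratio and
  60 patients per arm. Low-variance event times are required: with
  exponential times even a hazard ratio of 10 leaves exact-partition
  recovery near 50%, because noise dominates the cutpoint search. A
  structural property caps recovery even then: under strong separation the
  log-rank statistic is slightly larger for marginally unbalanced splits
  than for the true one, so whenever the latent high group's lowest-risk
  patient happens to be among its longest-lived, the maximizing cutpoint
  excludes that patient. This puts an honest ceiling of roughly 0.9 on
  exact-partition recovery regardless of sample size or separation — a
  property of max-statistic cutpoint selection worth knowing when
  interpreting stratified cohorts, and the same mechanism that motivates
  the mandatory selection-bias caveat.

## Numerical choices and degenerate inputs

* Pair enumeration uses a KD-tree radius query, so only pairs within the
  maximum grid radius are materialized; K̂ values are assembled from a
  cumulative sum over distance-sorted pairs.
* The brute-force oracle used in the tests computes edge weights by an
  independent route (explicit angular-interval unions) and agrees with the
  production inclusion–exclusion geometry to ~1e-12; a dense angular
  sampling oracle (65536 steps) validates both to its own discretization
  error (~1e-4 tolerance).
* k-NN distance ties everywhere are broken by cell order; the k-NN query
  fetches 8 spare neighbors so rank-k ties can be re-broken exactly.
* Patient k-fold assignment shuffles patients with the scheme seed and
  splits into nearly equal folds; generators derive per-sample seeds from
  one root generator, so datasets are bit-reproducible given the config
  seed and distinct seeds decorrelate.
* Empty feature groups, all-censored outcomes, absent cell types, all-zero
  or negative marks, zero-variance biomarkers, infeasible hardcore packing
  and equal-risk stratification all fail fast with specific errors (or a
  warning where a safe default exists, as for zero variance).

## Known limitations

* The isotropic correction assumes a rectangular window; irregular tissue
  boundaries are approximated by the bounding box, which under-corrects
  for cells near a concave tissue edge.
* Inhomogeneous and cross-type (bivariate) K-functions, Cox models,
  competing risks and covariate-adjusted stratification are out of scope.
* The stratified log-rank p-value is intentionally reported without
  selection adjustment, flagged by the caveat; treat it as descriptive.
* Community detection at resolution 1.0 over-partitions homogeneous data
  (resolution limit); cluster counts are not evidence of structure on
  their own.
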