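# Methods

`ptcrad` implements a multimodal MRI radiomics pipeline for binary tumor
aggressiveness prediction: per-modality feature extraction, sparse-
representation feature selection, and a projective dictionary-pair
classifier, evaluated with the standard clinical metric panel. This note
documents the models, conventions, defaults and their rationale, and what
the synthetic data can and cannot show.

## Pipeline overview

Each case consists of three co-registered 3D volumes — contrast-enhanced
T1-weighted (CE-T1WI), T2-weighted (T2WI) and diffusion-weighted (DWI)
imaging — plus a binary tumor mask and a label in
{aggressive, non_aggressive}. The flow is:

1. extract 528 features per modality (1584 for the three concatenated);
2. split the cohort stratified ~2:1 into a cross-validation set and a
   held-out test set;
3. on the cross-validation set only: rank features by L0 sparse-regression
   weights, then pick the best prefix subset by cross-validated accuracy
   of the dictionary-pair classifier (sizes 5..100);
4. train the classifier on the full cross-validation set with the chosen
   subset; report AUC/ACC/SEN/SPE/PPV/NPV with 95% CIs on both splits.

Standardization, screening, selection and dictionary training only ever
see cross-validation rows; fitted objects carry the case ids they were fit
on so leakage is testable.

## Feature set (528 per modality)

* **18 first-order** statistics of the raw ROI intensities (entropy and
  uniformity on the discretized histogram). Population (ddof=0) moment
  conventions; constant/single-voxel ROIs define skewness/kurtosis as 0,
  entropy 0, uniformity 1.
* **15 shape** descriptors of the mask: volume (voxel count x voxel
  volume), surface area, surface-to-volume ratio, sphericity,
  compactness-1, spherical disproportion, maximum 3D diameter, maximum 2D
  diameter in the three orthogonal planes, principal axis lengths
  (4*sqrt(eigenvalue) of the coordinate covariance), elongation, flatness.
  Compactness-2 is deliberately omitted: it equals sphericity cubed, and
  the set is fixed at 15 non-redundant members. The surface mesh comes
  from marching cubes on the indicator lightly smoothed with a 0.5-voxel
  Gaussian; on a raw binary mask the staircase artifact overestimates a
  digital ball's area by ~9%, while the smoothed mesh is within ~4% and
  biased conservatively (sphericity stays <= 1). Diameters are computed
  over mesh vertices via their convex hull; single-voxel masks report 0.
* **39 texture** features from four gray-level matrices built on the
  discretized ROI (below): 8 GLCM, 13 GLRLM, 13 GLSZM, 5 NGTDM, with
  member lists following common IBSI-consistent usage (exact names in
  `features/texture.py`).
* **456 wavelet** features: one single-level 3D discrete wavelet transform
  (default `coif1`, periodization mode) produces 8 subbands (LLL..HHH); on
  each subband the 18 first-order + 39 texture features are recomputed
  (57 per subband). Shape features are not recomputed on subbands — mask
  geometry does not change under filtering, which is also why 57 = 18+39.
  The mask is aligned to the half-resolution subband grid by
  nearest-neighbor downsampling (every second voxel).

Feature names are `{modality}.{original|wavelet-XXX}.{family}.{name}`.

### Discretization

Fixed-bin-count quantization (default 32 bins) per ROI per (sub)image:
level = ceil((x - min)/w) with w = (max-min)/n_bins and the minimum mapped
to level 1 — right-closed bins, so e.g. {1,5,9} with 2 bins maps to levels
{1,1,2}. Fixed bin *count* (rather than fixed width) keeps the level range
comparable across modalities with different intensity scales, including
wavelet subbands whose scales differ per band. A constant ROI maps to a
single occupied level; downstream features then take documented degenerate
limits rather than erroring (GLCM energy 1, contrast 0, correlation 1;
NGTDM coarseness capped at 1e6, busyness/strength 0).

### Texture matrix conventions

* GLCM: distance-1 offsets over the 13 unique 3D directions; each
  directional matrix symmetrized and normalized, then averaged over
  directions with at least one in-mask pair ("matrix-averaged"
  aggregation). Features are computed on the averaged matrix.
* GLRLM: runs of constant gray level along the same 13 directions,
  restricted to mask voxels (a masked-out voxel breaks a run); directional
  count matrices are summed. RunPercentage divides by
  n_voxels x 13 so it stays in (0,1] under merged counts.
* GLSZM: 26-connected zones of constant gray level (direction-free).
* NGTDM: Amadasun-King components with the neighborhood = the 26-neighbors
  inside the mask; voxels with at least one masked neighbor contribute.

An independent brute-force enumerator (plain loops over voxels and
directions, in `tests/oracles.py`) reproduces all four matrices exactly on
a fixture set of small grids, including one with an interior masked-out
hole.

## Feature selection

Importance is the magnitude of the L0-penalized least-squares coefficient:

    w_hat = argmin_w ||y - F w||^2 + gamma ||w||_0,   gamma = 0.1,

with y in {-1,+1} and standardized columns. The problem is NP-hard; the
solver is greedy orthogonal forward pursuit (atoms enter by residual
correlation, full least-squares refit each step) taking the
penalized-objective argmin along the path, followed on small problems
(|support| x n_features <= 20000) by an add/delete/swap local refinement.
On well-posed sparse-recovery instances with <= 12 candidates the solution
matches exhaustive support enumeration to 1e-9 (verified over hundreds of
seeded instances; the refinement bound keeps the large-p pipeline cost
linear). Zero-variance columns are excluded with a warning. Ties in |w|
rank by lower column index.

The subset is then chosen by a cumulative sequential forward search:
prefixes of the ranking from size 5 to 100 are scored by stratified 5-fold
cross-validated accuracy of the dictionary-pair classifier (fold
standardization learned on training folds only, folds fixed by seed); the
highest accuracy wins, smallest size on ties.

## Dictionary-pair classifier

Per class c a synthesis dictionary Psi_c (p x K) and analysis dictionary
Phi_c (K x p) minimize

    sum_c ||F_c - Psi_c A_c||_F^2 + tau ||A_c - Phi_c F_c||_F^2
          + lambda ||Phi_c Fbar_c||_F^2,    s.t. ||psi_q||^2 <= 1,

(lambda = 0.01, coupling tau = 1.0, A_c the auxiliary coding matrix of the
standard relaxation, Fbar_c the complement samples). Alternating updates:
A_c and Phi_c are exact ridge solutions (a 1e-8 Tikhonov term on Phi_c is
part of the tracked objective, so every block update is an exact
minimizer); Psi_c takes five projected proximal-gradient steps with step
size 1/||A_c A_c^T||_2 and column projection onto the unit ball, which
guarantees the objective trace is non-increasing. Initialization is a
seeded draw of unit-norm atoms; the fit is invariant to sample order.
Test cases get the label with the smallest reconstruction residual
||f - Psi_c Phi_c f||_2; ties (< 1e-12) go to the larger training class,
then the lower class index. The ROC score is r(negative) - r(positive),
a monotone transform of the decision rule.

Two structural choices matter and were made on first principles:

* **Bias augmentation.** The residual is an even function of f, so after
  z-scoring, two classes that differ only by a mean shift have antipodal
  means (+mu, -mu) and *identical* residual distributions — no linear
  reconstruction operator can separate them. A constant bias component
  (value 1, homogeneous-coordinate convention) is appended to every
  standardized sample by default, breaking the sign symmetry so the
  dictionaries can encode class means. For data separated by span rather
  than mean (e.g. the orthogonal-subspace test construction) it can be
  disabled.
* **Atom count.** K defaults to min(15, smallest class size, feature
  dimension): 15 is a conventional dictionary-learning scale for designs
  with tens of selected features, and K >= dimension would make
  reconstruction perfect for every class and destroy discrimination.

## Evaluation

* Proportion CIs: exact Clopper-Pearson. AUC CI: DeLong variance, normal
  interval on the logit scale (degenerate AUCs 0/1 collapse to a point).
* AUC: Mann-Whitney with ties counted 1/2 (equals the trapezoidal
  empirical-ROC area); verified against an exhaustive pair-count oracle.
* DeLong comparison: two-sided paired test from structural components via
  midranks; identical or rank-equivalent scorings return p = 1 by
  convention. Type-I error is calibrated in the suite (1000 null
  replicates at n = 200, rejection rate required in [0.03, 0.07]).
* Univariate screen: per-column Welch t-tests (unequal variances is the
  safer default when only "t-test" is specified); columns constant in both
  classes report P = 1.
* Unsupervised check: Ward agglomerative clustering (deterministic — no
  random initialization) of cases on standardized screened features into
  two groups, mapped to labels by the better of the two permutations.
* Split: stratified random, train share = round(n x fraction) allocated
  per label by largest remainder; a 107-case cohort at the ~2:1 fraction
  yields exactly 71/36.

## Synthetic phantoms

No public imaging cohort accompanies this analysis, so the generator
emulates the statistical structure the pipeline needs:

* **Lesion geometry**: one mildly anisotropic ellipsoid per case (per-axis
  factors U(0.75,1.25) normalized to unit geometric mean), diameter drawn
  from a class-conditional truncated normal — defaults 13.08 +/- 6.44 mm
  (aggressive) vs 9.36 +/- 3.86 mm (non-aggressive), floored at the 5 mm
  inclusion threshold, echoing the reported cohort; lesions that cannot
  fit the grid are rejected with a clear error.
* **Intensity**: background 100 plus a per-modality in-lesion contrast of
  1.5-2.5 x noise_sd (DWI brightest), plus a class shift of
  intensity_effect x noise_sd (default 1.5) for aggressive cases.
* **Texture**: Gaussian random fields, correlation length 1 voxel for
  non-aggressive and 1 + texture_effect (default 1.5) voxels for
  aggressive cases, normalized to unit variance so the texture signal is
  orthogonal to the intensity signal; GLCM/GLRLM-type features detect the
  difference without any feature being hand-tuned.
* **Inter-modality correlation**: the three channels mix a shared latent
  field with channel-specific fields (default rho = 0.5), as co-registered
  sequences of one tumor are correlated.
* Default grid 64^3 at 1 mm isotropic spacing: desk-scale extraction while
  leaving hundreds of lesion voxels.

A direct feature-table simulator (`generate_feature_table`) skips imaging:
informative columns are within-class unit-variance normals with a
between-class mean gap (the planted effect), the rest standard normal.

The **null configuration** (`null_config`) zeroes the texture and
intensity effects *and* equalizes the class diameter distributions —
lesion size is itself a class signal by default — so the class-conditional
generative distributions are identical and any classifier can only attain
chance accuracy. Everything is driven by `numpy.random.default_rng(seed)`
and is byte-reproducible across platforms.

What the phantoms do **not** model: MR physics (no k-space, coil or
diffusion modelling), anatomy (no organ context, single lesion per case),
realistic thyroid texture (no quantitative description of real PTC lesions
exists to calibrate against), segmentation noise, or scanner/center
effects. Passing tests therefore demonstrate correctness and calibration
of the machinery under known ground truth, not clinical performance.

## Problem sizes used by the tests and acceptance script

Chosen for desk-scale runtime while keeping the statistics meaningful:

* strong-effect end-to-end runs: 30 cases/class at 48^3 (acceptance
  script) and 12/class at 32^3 (unit suite), intensity effect 3 with noise
  sd 5 — far above threshold, so a correct pipeline should approach
  perfect test accuracy (the in-lesion mean alone is Bayes-separable).
* null end-to-end run: 100 cases/class at 32^3, combined model; test
  accuracy is required to sit inside the 99% binomial band around 0.5.
* calibration: 1000 DeLong replicates at n = 200; the t-test null screen
  uses the planted table (200 x 1000 independent columns) because
  image-derived radiomics columns are strongly correlated and a binomial
  band on their pass count would be invalid.
* the multi-seed combined-vs-single-modality comparison is run
  single-seed with a 0.05 AUC margin in the suite; the acceptance script
  reports combined and best-single test AUCs for one seed.

## Known limitations

* The exact historical membership of each feature family is not uniquely
  fixed by the printed counts; this package documents its member lists
  name-by-name and treats the counts (18/15/8/13/13/5/57/456/528/1584) as
  the binding contract.
* The L0 solver is a heuristic; its oracle-equivalence guarantee is
  empirical and limited to small, well-posed instances.
* The DPL objective is non-convex; only monotone descent to a stationary
  point is guaranteed.
* Forward-search best-subset accuracy is an optimistic estimate of
  generalization (maximum over 96 correlated estimates); the held-out test
  split exists precisely to measure honest performance.
* No inter-modality registration or resampling: inputs are assumed
  co-registered and equally sampled, as in the source protocol.
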