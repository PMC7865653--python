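# Methods

This note documents the models, conventions and design choices behind
`lesionrad`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic phantoms do and do not show
about real data.

## Synthetic cohort model

The phantom generator emulates the statistical structure of a
contrast-enhanced MR radiomics study of liver metastases, not the imaging
physics. Per patient:

- **Label.** Bernoulli with `mutant_fraction` (default 41/76, matching the
  mutation prevalence the analysis design assumes).
- **Lesion count.** 1–15 lesions; a single lesion with probability 0.579,
  otherwise a truncated-geometric draw (ratio 0.4) over 2..15, so most
  multi-lesion patients carry a few lesions and large counts are rare.
  This reproduces a cohort mean of roughly 1.7 lesions per patient.
- **Shape.** Each lesion is an ellipsoid with a log-normal anisotropy
  (σ = 0.15, normalized to preserve the equivalent diameter), target
  equivalent diameter uniform within 18–54 mm, plus a smooth random radial
  deformation (6% of the radius, correlation length 2 voxels). Shape
  parameters are drawn *identically for both classes*: by construction
  morphology carries no class signal, which turns "morphology does not
  separate the classes" into a testable property of the downstream stages.
- **Intensity.** Default voxel spacing (1.2, 1.2, 3.0) mm (an axial
  in-plane resolution with 3 mm slices; the true acquisition spacing of any
  given study is configurable, not claimed). Nine contrast phases by
  default; each phase has a smooth enhancement level (sinusoidal profile
  across phases, ~110 ± 35 intensity units, with per-phase jitter) plus an
  in-lesion Gaussian random field: white noise smoothed with a Gaussian
  kernel and rescaled to SD 25. The kernel width (correlation length) is
  0.7 voxels for the mutant class and 0.7·(1 + 0.35·`texture_effect`) for
  wild type. `texture_effect = 0` therefore makes the classes exchangeable;
  the default `texture_effect = 1` was calibrated once so that per-class
  means of GLCM contrast separate by ≥ 2 pooled SDs, and is not revisited.
- **Second reader.** The signed Euclidean distance transform of the mask is
  perturbed by a smooth unit-variance field scaled by `reader_perturbation`
  (voxels, default 0.5) and re-thresholded: a random, spatially coherent
  dilation/erosion of the boundary. Zero perturbation reproduces the mask
  exactly; the default keeps Dice well above 0.8.
- **Reproducibility.** One global seed spawns a `SeedSequence` substream
  per patient, so enlarging a cohort never reshuffles existing patients.

What the phantoms do **not** model: liver background anatomy, partial
volume and bias fields, contrast-agent kinetics, inter-phase motion,
rim/core enhancement structure, or correlated multi-lesion biology. Passing
tests on phantoms therefore demonstrate the *pipeline's* statistical
behavior (calibration under the null, power under a known signal, immunity
to leakage), not clinical performance on real CE-MRI.

## Preprocessing

Default chain, applied per lesion and phase: resample to cubic voxels at
the finest native spacing (linear interpolation for the image; the mask is
linearly interpolated as a [0,1] field and re-thresholded at 0.5), no
wavelet re-weighting (weight 1), fixed-bin-number quantization with
N<sub>g</sub> = 32 over the in-mask min–max. Out-of-mask voxels never
influence bin edges and carry a 0 sentinel excluded from every matrix.
Equal-probability (quantile) binning and a single-level `sym8` wavelet
band-pass re-weighting (the six mixed low/high sub-bands scaled, LLL and
HHH untouched) are config-exposed alternatives. A constant lesion maps to
level 1 and is flagged in provenance rather than raising.

## Texture features (48)

Nine first-order statistics on the continuous in-mask intensities (mean,
mode, median, SD, median absolute deviation, range, kurtosis as the plain
fourth standardized moment, skewness, IQR with linearly interpolated
quantiles), plus 39 matrix features:

- **GLCM (8).** Symmetric, merged over the 13 unique distance-1 3D
  directions (counts accumulated, then normalized once — not averaged per
  direction): energy, contrast, correlation, homogeneity, variance, sum
  average, entropy, dissimilarity. Entropy uses the natural log by default
  (base-2 available); which convention a given historical toolbox used is
  not always documented, so the base is explicit in the config.
- **GLRLM (13).** Runs merged over the same 13 directions: SRE, LRE, GLN,
  RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLV, RLV. Naming
  follows the standard convention — RLN squares the run-length marginals
  and GLN the gray-level marginals. Run percentage is normalized by
  voxels × directions so RP ∈ (0, 1] for the merged matrix.
- **GLSZM (13).** 26-connected zones; the same 13 formula shapes with zone
  size in place of run length; ZP = zones/voxels.
- **NGTDM (5).** 26-neighborhood means with incomplete neighborhoods at the
  mask edge using the neighbors that exist: coarseness, contrast, busyness,
  complexity, strength. Strength is defined as 0 when Σsᵢ = 0;
  coarseness is undefined (NaN) when Σpᵢsᵢ = 0.

Degenerate-lesion values (e.g. GLCM correlation of a constant lesion)
propagate as NaN, never as silent zeros. Patient-level aggregation is the
nested median: median across phases within each lesion, then across
lesions.

The vectorized constructions (pair counting by array shifts; run-length
encoding of lexicographically linearized lines; per-level connected
components; convolutional neighborhood means) are verified against
independent brute-force enumerations to 1e-10 in the test suite.

## Morphology features (15)

Volume (voxel count × voxel volume), surface (marching-cubes mesh on a
slightly smoothed indicator — σ = 0.7 voxels, which removes the staircase
bias of meshing raw binary data; voxel-face counting available, which
overestimates a sphere's area by ≈ 1.5×), circularity (area of the
volume-equivalent sphere over the actual surface; 1 for a sphere),
irregularity (1 − circularity), compactness (S²/V), rectangularity
(V over the axis-aligned bounding box volume), convexity (convex-hull
surface over lesion surface), radial-profile statistics from the distances
of 6-boundary voxels to the physical centroid (average, SD, entropy in
bits of the normalized radii, sphericity = R_avg/R_sd, roughness =
(m₄^¼ − m₂^½)/R_avg from the central moments, smoothness = mean absolute
second difference of contour radii ordered by polar angle per axial
slice), eccentricity (largest chord over the largest chord orthogonal to
it, from hull vertices), and elongation.

Two source ambiguities were resolved as follows and are worth flagging.
First, the feature list is described as 15 strong but only 14 distinct
definitions are given; the radial-length SD — which the sphericity ratio
already requires — is reported as the 15th feature. Second, the printed
sphericity and convexity definitions appear conflated in the source
material; each is implemented from its prose description (sphericity as
the radial ratio, convexity as the hull-area ratio). Note this radial
"sphericity" is *not* the mesh-based sphericity of some toolkits — that
quantity is what this package calls circularity.

Elongation is the aspect ratio of the minimum-area enclosing rectangle per
slice (rotating-calipers over hull edge directions, plus a half-voxel
footprint margin), averaged over nonempty slices within each of the three
orthogonal stacking directions; the reported value is the **maximum**
across the three directions. The maximum is deliberate: slices
perpendicular to a prolate lesion's long axis are circles, so averaging
across directions would cap the score well below the true axis ratio
(a 3:1 ellipsoid would score ≈ 1.8; the max convention recovers ≈ 3).

## Stability and univariate screening

ICC(2,1) — two-way random effects, absolute agreement, single measurement —
is computed directly from the ANOVA mean squares of the patients × readers
layout; ICC(3,1) (consistency) is available. Zero-variance layouts give
NaN (undefined agreement), and NaN is never retained by the filter.
Features pass at ICC ≥ 0.8 (threshold exposed). Retained features are
screened for a lesion-size effect: Wilcoxon between patients whose largest
lesion's equivalent diameter is < 20 mm vs ≥ 20 mm (the largest lesion
resolves multi-lesion patients; the screen is skipped with a warning when
a group has < 2 patients). Stability is computed on per-patient aggregated
values, consistent with the per-patient design of every other stage.

Mann–Whitney: midrank ties; exact two-sided p by full enumeration of group
assignments for combined n ≤ 12 (valid under ties), normal approximation
with tie-corrected variance above. ROC: empirical over observed
thresholds, oriented so AUC ≥ 0.5 with the orientation recorded (the
direction convention of a given study is rarely stated, so it is explicit
here); AUC equals U/(n₁n₀) to machine precision by construction. Youden
ties break toward higher specificity — arbitrary but fixed. AUC CI by
DeLong (default) or bootstrap. FDR control by Benjamini–Hochberg
(`statsmodels`); significance means adjusted p < 0.05.

## Multivariate analysis

LASSO on the standardized features with the 0/1 label as a squared-error
response — matching a selection criterion stated in terms of
cross-validated mean squared error rather than deviance — with the penalty
weight minimizing the mean 10-fold CV MSE (seeded `KFold`); nonzero
coefficients survive. Constant columns are dropped with a warning.

Classifier families and the hyperparameters the design leaves open (all
config-exposed): LDA; SVM with RBF kernel and inner-CV cost selection over
{0.1, 1, 10}; KNN with k tuned over {3, 5, 7, 9} by inner CV; a
single-hidden-layer MLP as wide as the predictor set; a decision tree of
depth ≤ 4. Evaluation is stratified 10-fold CV with patients as the unit;
standardization lives inside the pipeline so it is re-fit within every
training fold. Reported per model: median and 2.5–97.5 percentile interval
of fold-level AUC/ACC/SEN/SPEC. Folds that degenerate to a single class
are skipped (AUC undefined); the fold count shrinks automatically when a
class has fewer members than folds. The winner has the highest median AUC,
ties broken by median ACC. External validation refits the winner on the
full training cohort and scores the held-out cohort once; confusion-matrix
metrics are exact arithmetic.

## Pipeline

`run_all` wires the stages together with a label-stratified, seeded
train/validation split (default 24 validation patients out of 76, mirroring
a 52/24 design), archives the config, writes tidy CSV feature tables, the
stability report, the ROC table and model reports, and checksums every
artifact; identical configs reproduce identical checksums. Stage failures
abort with a stage-named error.

## Problem sizes in the automated checks

The acceptance checks run at sizes chosen to keep the full suite fast on a
single CPU while preserving each check's meaning: the null-calibration
cohort uses 76 patients, 1–3 lesions, 3 phases; signal-recovery replicates
use 30 patients, 1–2 lesions, 2 phases over 20 seeds, with the classifier
comparison on a 60-patient cohort; oracle equivalence uses 50 random
lesions within 12³ voxels. The generator's cohort-level defaults (nine
phases, 1–15 lesions) remain as stated above for study-scale runs.

## Known limitations

- Texture distances > 1 and 2D (slice-wise) texture modes are out of scope.
- The surface mesh uses a fixed smoothing width; very small lesions
  (a few voxels) fall back to face counting.
- NGTDM busyness/contrast/complexity are set to 0 when only one gray level
  is present (their defining sums are empty).
- The exact-enumeration Wilcoxon is O(C(n, n₁)) and intentionally capped
  at combined n = 12.
- Phantom realism is limited to second-order intensity structure; see the
  cohort-model section for everything it does not emulate.
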