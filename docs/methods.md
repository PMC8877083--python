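# Methods

This note documents the models, parameter choices and numerical decisions
behind `deltarad`, in the order the pipeline runs.

## Problem setting

Patients with a solid tumour receive induction chemotherapy (IC). Each patient
has multi-parametric MRI at two timepoints — baseline and after the first IC
cycle (~3 weeks) — with up to three modalities: T1-weighted, T2-weighted and a
DWI stack from which an ADC map is computed. A single 3D ROI is drawn on the
T2w volume (the modality with the best tumour contrast and full availability)
and propagated to the other grids. The target is the binary end-of-treatment
response class (responder = partial/complete response; non-responder =
stable/progressive disease). The predictive features are *early deltas*: the
difference between the post-cycle-1 and baseline values of each radiomic
feature.

## Preprocessing

**ADC fitting.** Under mono-exponential diffusion decay, S(b) = S0·e^(−ADC·b),
so ln S is linear in b and ADC is minus the OLS slope, fitted voxelwise over
all b-values. Nonpositive signal samples (possible in noisy or masked data,
where the log is undefined) are excluded from that voxel's fit; a voxel left
with fewer than two valid samples, or without two distinct b among them, is
flagged invalid, set to 0 and excluded from downstream ROI statistics. The fit
is invariant to rescaling of S0 by construction. ADC units are mm²/s; typical
tissue values are ~1×10⁻³ mm²/s.

**Intensity normalization.** T1w/T2w intensities are on arbitrary scanner
scales, so the range [volume minimum, 98th percentile] is mapped affinely onto
[0, 5000], with values above the anchor clipped to 5000. The percentile is
computed over the whole volume (linear interpolation); restricting it to a
body mask is a reasonable alternative and the anchor is exposed as a
parameter. ADC maps are *not* normalized — they are already in physical units.
A constant volume has no usable anchor and is rejected.

**Resampling.** All volumes are resampled to an isotropic 2 mm grid so that
spacing-dependent texture and shape features are comparable across patients.
Continuous volumes use cubic B-spline interpolation; binary masks use nearest
neighbour, since B-spline interpolation of a binary image produces non-binary
values. The output grid keeps the input origin and covers the input physical
extent (size = ⌈extent/2 mm⌉), with nearest-neighbour extrapolation at the
border so that, e.g., constant volumes stay constant. Grids are assumed
co-registered; no registration step is included.

**ROI propagation** is nearest-neighbour lookup in physical coordinates from
the target grid into the T2w-mask grid; an empty result (disjoint extents) is
an error.

**Order of operations:** ADC on the native DWI grid → normalization (T1w/T2w
only) → resampling → ROI propagation.

## The 536-feature vector

Per (volume, mask) pair: 14 shape, 18 first-order, 24 GLCM + 16 GLRLM = 40
texture features on the original image, and 18 + 24 + 16 = 58 first-order +
texture features on each of the 8 sub-bands of a first-level wavelet
decomposition (464), for 536 total. Definitions follow the IBSI conventions;
the canonical names are in `deltarad.features.FEATURE_NAMES`.

Numerical choices:

* **Discretization** — fixed bin *count* (default 32) over [min, max] of the
  ROI values of that image; the maximum maps to bin 32; a constant ROI
  occupies a single level (degenerate but legal texture).
* **Texture matrices** — built per direction over the 13 unique distance-1 3D
  offsets, normalized, features computed per direction and averaged.
  Directions with no voxel pair are skipped; a single-voxel ROI has no GLCM at
  all, and its texture features propagate as NaN ("flagged missing"), to be
  imputed with the train-set feature mean during modelling. GLCM features are
  computed on the grey levels actually present (matrix restricted to occupied
  rows/columns). Out-of-ROI voxels break GLRLM runs.
* **Wavelet** — first-level *undecimated* (stationary) 3D transform with the
  `coif1` family and symmetric padding of odd axes; the 8 sub-bands stay on
  the original grid, so the ROI mask applies directly, and each band is
  discretized independently.
* **Shape** — mesh volume and surface area from a marching-cubes isosurface of
  the (padded) mask. The raw voxelized isosurface overestimates surface area
  (staircase effect), biasing sphericity low, so the mesh is smoothed with 10
  Taubin iterations (volume-preserving to ~1%); tiny ROIs (<100 faces) skip
  smoothing to avoid mesh collapse. Axis lengths are 4·√λ of the physical
  voxel-coordinate covariance eigenvalues; elongation = √(λ₂/λ₁), flatness =
  √(λ₃/λ₁). Maximum diameters use convex-hull-reduced boundary-voxel centres.
* **Delta tables** are element-wise post − baseline with matching column
  order; patients lacking either timepoint drop out of that modality's table
  (mirroring real availability, where modality counts differ between models).

## Signature modelling

Per modality, the delta table enters 100 (default; 25 in the reduced-scale
configuration used by the test suite and demo runs, chosen to keep runs short
while leaving the Monte-Carlo error of the averaged metrics at a few percent)
independent stratified 55/25/20 train/validation/test splits. Fractions are
applied per class with rounding; on very small classes the rounding can leave
an empty test set, in which case one member is moved from validation (then
train) so every class appears in the test set. The splits are random
sub-samples *without* replacement — the repeated-split reading of
"bootstrapping" — since 55/25/20 partitions are specified, not resamples.

Within one repetition, fitted strictly on the training rows:

1. **Stability whitelist** (optional): a configured list of feature names that
   are robust to acquisition-parameter changes; identity when not configured.
   The published per-modality lists (279 T1w / 387 T2w / 256 ADC names) are
   accepted as external configuration, not recomputed.
2. **Z-score** with train mean and population SD; zero-SD columns map to 0.
   Missing values are imputed with the train column mean beforehand (0 after
   standardization).
3. **Rank-sum preselection**: two-sample Mann-Whitney/Wilcoxon test per
   feature (normal approximation with tie correction — adequate at these
   sample sizes), keep p < 0.05. If nothing passes, the 5 smallest-p features
   are kept so the PCA is never empty (logged).
4. **Semi-supervised PCA**: PCA on the preselected standardized features; keep
   the smallest k whose cumulative explained-variance ratio reaches 0.97. The
   transform is stored and applied unchanged to validation/test rows.
5. **SFFS** over the k components: forward-add the component maximizing the
   validation accuracy of a linear SVM trained on the training projections,
   then float — remove components while removal strictly improves the best
   accuracy recorded for the smaller size. Ties break toward the lowest
   component index; the returned subset is the best-accuracy subset visited
   (smallest size on ties). With no cap, up to all k components may be
   explored. An empty validation set (degenerate tiny split) disables
   selection and keeps every component.
6. **Linear SVM** (C = 1.0; kernel and C are configuration). The paper-style
   signature is the signed decision value, oriented so positive = responder;
   hard labels threshold at 0. The kernel choice is a default, not a claim
   about the original implementation, which did not state one.

Leakage is excluded by construction and by a mutation test: perturbing
test-set rows changes no fitted parameter in any repetition.

## Evaluation and fusion

* Per-repetition test accuracy/TPR/TNR are averaged (±SD) over repetitions.
* The primary AUC is the single ROC of each patient's **median test
  signature** across the repetitions in which they fell in the test set;
  per-repetition AUC means are also available. AUC uses the rank formulation
  (ties ½); the 95% CI is a stratified percentile bootstrap (2000 resamples,
  seedable).
* **Fusion**: per-modality median signatures are standardized across patients
  (raw decision values of different SVMs are not commensurable) and averaged
  over the modalities available to each patient, so ADC missingness reduces a
  patient's fusion to the modalities they have; a single modality passes
  through unchanged.
* **AUC comparison** uses the paired DeLong covariance-adjusted z-test,
  implemented in-package (replacing the external web calculator used
  historically for this purpose); degenerate zero-variance comparisons return
  p = 1 for equal AUCs.
* **Comparators**: (i) the early radiological call used directly as a
  prediction (no training), with its confusion matrix and accuracy/TPR/TNR —
  on the printed counts (25 responders of whom 10 were called NR early; 1 of
  25 non-responders miscalled) this gives accuracy 0.78, TPR 0.60, TNR 0.96;
  (ii) a delta-volume-only SVM under the same split scheme (no
  PCA/SFFS needed for one feature).

## Synthetic data: what it emulates, and what it does not

The **feature-level generator** draws, per patient and modality, a
536-dimensional noise vector with block correlation (blocks of 8, intra-block
correlation 0.3 — radiomic features are strongly grouped in reality) and adds
`effect_size × noise_sd` to a random subset of columns (default 54, ~10%) for
responders. Defaults mirror the emulated study: 50 patients, balanced classes,
ADC rows present for exactly round(n·(1−0.32)) = 34 patients. A global seed
expands into per-patient substreams, so enlarging a cohort never changes
earlier patients' draws.

The **image-level generator** builds ellipsoidal tumours (radii 8–12 mm) with
Gaussian-random-field interior texture on a 48×48×32 grid at 1.5×1.5×2 mm.
After one cycle, responder volumes scale by 1−0.40 (non-responders 1−0.05),
responder texture loses contrast and correlation length, and responder ADC
rises by 35% (non-responders 5%) — the directions of change reported for
responding tumours. DWI stacks follow S(b) = S0·e^(−ADC·b) at b ∈ {0, 500,
1000} s/mm² with 1% multiplicative noise (scaled by `noise_sd`).

Passing tests on these cohorts demonstrate *parameter recovery and correct
machinery* — that the pipeline finds signal exactly when the generator plants
it, stays at chance on null cohorts (median test AUC within [0.35, 0.65]), and
recovers generating ADC and volume-change values. They do **not** reproduce
the clinical performance figures (e.g. test AUC 0.93 for ADC delta radiomics),
which were measured on private trial imaging with real tumour biology; no
synthetic texture model stands in for that. Realistic MRI physics (coil bias,
partial-volume effects, registration error) is deliberately out of scope.

## Known limitations

* GLCM/GLRLM definitions follow the common reference taxonomy, but small
  implementation-level conventions (handling of absent grey levels, direction
  weighting) vary between extractors; cross-extractor agreement beyond the
  documented conventions is not asserted.
* The stability whitelists are external configuration; without them the full
  536 columns enter the screen, which is statistically more permissive.
* Fusion standardizes signatures using all patients' median scores; this is a
  post-hoc calibration step, acceptable for score *combination* but not a
  train-only transform.
* The image-level generator's class differences are stylized; effect sizes at
  the feature level emerge indirectly and are not controlled per feature.
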