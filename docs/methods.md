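# Methods

## Problem and pipeline

The package quantifies focal loss of the photoreceptor ellipsoid zone (EZ)
in macular SD-OCT volumes.  A volume is indexed `(x, y, z)` — lateral
position in a B-scan, B-scan index, axial depth (increasing toward the
choroid).  Detection is a per-voxel binary classification restricted to the
EZ slab, wrapped by geometric pre-processing and anatomical post-processing:

    denoise → segment 11 surfaces → TPS smooth → flatten to surface 11
    → EZ VOI (surfaces 7–8) → 57 features/voxel → PCA(10)
    → under-sample + AdaBoost → vessel exclusion → morphological cleanup
    → volume = count × voxel volume

## Denoising

Speckle is the dominant OCT noise; each B-scan is filtered independently
with a bilateral filter (spatial σ = 3 px; range σ defaulting to 10% of the
slice dynamic range — both unstated quantities in the source method, chosen
as conventional values and exposed in `BilateralParams`).  The fast
implementation samples the range axis every `range_factor·σ_r/2` intensity
units, computes each sample's response with two Gaussian convolutions, and
interpolates linearly; with the default factors it agrees with the exact
double-loop bilateral sum to well under 1% at slice centres (tested at 2%).
Spatial grid downsampling (`spatial_factor`) is available for large scans.
The output of each slice provably stays inside the slice's intensity range
(weights are non-negative and normalized).

## Surface segmentation

Full 3D graph-search segmentation is replaced by a deliberately simple
per-surface search with the same contract (ordered, smooth surfaces):
for one surface, the column positions `z(x)` within a B-scan maximize the
summed polarity-signed axial gradient subject to `|z(x+1) − z(x)| ≤ 2`
voxels, solved exactly by dynamic programming per B-scan (verified against
exhaustive path enumeration on tiny inputs).  A two-level coarse-to-fine
scheme downsamples **only laterally**: axial downsampling would smear a
sharp boundary step by a parity-dependent amount and can invert the
saliency ranking between surfaces.

Search order: surface 1 (the vitreoretinal interface, strongest
dark-to-bright step), then surface 11 (RPE bottom, strongest
bright-to-dark step, the robust flattening reference), then surfaces 2–10
top-down inside the established band.  Already-found surfaces impose hard
bounds: at least `min_separation = 2` voxels between consecutive surfaces,
and at most a per-layer `max_separation` close to each layer's anatomical
thickness (+4 voxels of slack).  The cap matters most for the EZ slab
(8 voxels): where a lesion erases the surface-8 gradient the search cannot
wander into the outer retina.  Per-surface gradient polarity defaults
follow the usual reflectivity alternation (bright NFL, dark nuclear
layers, bright EZ/RPE) and are configurable.

Surfaces are then smoothed per surface by a thin-plate spline fitted on an
8×8 knot grid (knot values are local window means, which both denoises and
preserves affine surfaces exactly; regularization 0 by default, → best-fit
plane as it → ∞), re-ordered by a running maximum, and the volume is
flattened by integer A-scan shifts that put surface 11 at the median of
its rounded depths (edge-value padding; no interpolation).  Sub-voxel
surface positions are kept throughout; voxel membership rounds half toward
the deeper surface.  The VOI is the half-open slab `[round(z7), round(z8))`
per column, with a one-voxel floor.

## Features

All 57 features are computed on the min-max-normalized intensity volume
(normalization constants from the VOI voxels of that volume).  Computing on
raw instead of normalized intensities would only rescale the first five
features affinely — PCA standardization absorbs the difference — but the
normalized choice makes the GLCM quantization (8 equal bins over [0, 1] by
default; the bin count is configurable) volume-independent.

The 13 directions are the half-axes of the 26-neighbourhood, parameterized
by `(α₁, α₂)` — α₁ the angle of the X–Y-plane projection from the X axis,
α₂ the angle from the Z axis.  Twelve pairs are the conventional listing;
the thirteenth, `(−45°, 45°) ↔ (1, −1, 1)`, is the unique half-axis those
twelve leave uncovered.  GLCMs are built per 5×5×5 block (cropped at
volume borders), offset one grid step, accumulated symmetrically,
normalized to probabilities; pairs with a member outside the block are
skipped, and a pairless (degenerate) matrix takes the constant-block
conventions (contrast 0, correlation 0, energy 1, homogeneity 1).
Correlation of a zero-variance GLCM is defined as 0.  The absolute
difference features aggregate the 13 directional differences by their mean
(max and sum are available); out-of-volume neighbours are clamped to the
nearest voxel.  The vectorized extractor is tested to 1e-10 against
brute-force per-voxel recomputation.

PCA standardizes each feature (zero-variance columns pass through as
zeros) and keeps the first 10 components, warning if they explain less
than 90% of the variance.

## Classification

Labels are +1 (disrupted) / −1 (intact).  Training balances classes by
keeping every minority sample and drawing an equal number of majority
samples uniformly without replacement (one draw per model, seeded).  The
classifier is classic discrete AdaBoost over depth-1 stumps on the 10 PCA
scores: per round the stump minimizing the weighted error over all
features and split midpoints, `α = ½ln((1−ε)/ε)` with ε clamped to
`[1e-10, 1−1e-10]`, multiplicative weight update with renormalization, and
early stopping at ε ≥ 0.5 or ε ≤ 1e-10.  `T = 100` rounds by default — the
weak-learner family and round count are free choices here; stumps and 100
rounds are the standard baseline.  Prediction is the sign of the weighted
vote, ties to non-disrupted.

The leave-one-out driver holds out one eye at a time, fits the PCA model
on the training eyes' voxels only (asserted by a leakage-canary test),
pools their disrupted voxels before under-sampling, and classifies every
VOI voxel of the held-out eye.  Per-fold balancing is available as a
config alternative to pooled balancing.

## Post-processing

Vessel silhouettes — shadows of inner-retinal vessels — darken the EZ just
like disruption.  The outer retina (surfaces 8→11) is projected en face
(mean over the slab per column), and a KNN classifier (k = 15) labels each
pixel from four standardized features: intensity, 9×9 local mean, 9×9
local std, and the maximum dark-line filter response over four
orientations.  The detector trains on labelled synthetic projections
generated from the phantom model with a fixed fixture seed; candidate
pixels must additionally be darker than the image median, and components
under 5 px are dropped.  Detected disruption components that touch the
vessel map are removed wholly when they lie entirely within the 2-px
dilated map, otherwise only the overlapping columns are cleared (a
column-only mode exists).

Morphological cleanup defaults to the en face footprint with a radius-5
disk, opening then closing (the open–close filter is idempotent), with
each column's EZ voxels set or cleared together; a literal 3D ball element
is available but note a radius-5 ball cannot fit inside an EZ slab only a
few voxels thick, which is why the 2D footprint is the default.  The
radius-5 element sets a hard floor on detectable lesion size: any detected
component whose footprint cannot contain an 11-px disk is erased.

## Evaluation

Voxel counts are restricted to the VOI (the classifier is defined only
there): SEN = 100·TP/(TP+FN), SPE = 100·TN/(TN+FP), BAR = (SEN+SPE)/2.
Eyes with no true disruption have undefined SEN/BAR (reported as missing,
never as 0 or 100).  Cohort statistics use the Student-t 95% CI; Pearson r
comes with a Fisher-z CI; Bland–Altman limits are mean ± 1.96·SD of the
differences; the two-sample t-test is pooled-variance by default (Welch by
flag).  FP denotes false positives throughout (one widely-copied
formulation mislabels it).

## The synthetic phantom

The generator renders what the pipeline *relies on*, not OCT physics:

* ten stacked layers with constant mean reflectivities
  (0.85, 0.25, 0.52, 0.18, 0.42, 0.20, **0.90 (EZ)**, 0.30, 0.60, 0.80;
  vitreous 0.02, choroid 0.10).  The ranking is chosen so the saliency
  structure matches real scans: the vitreous→NFL step is the strongest
  dark-to-bright gradient, RPE→choroid the strongest bright-to-dark, the
  EZ the brightest band, and each surface's own boundary is the strongest
  same-polarity gradient within its anatomical search band;
* surface geometry = per-layer base depths + a low-frequency sinusoid
  (amplitudes 3 and 2 voxels along x and y) + a radial-Gaussian foveal dip
  (8 voxels deep, σ = 0.15·nx, physically isotropic) applied to the inner
  six surfaces with decaying weights;
* EZ lesions: en-face discs (2 per trauma eye, radius 7–10 px) replacing
  the EZ-band intensity by 0.3× its reflectivity.  Lesions are
  rejection-sampled away from vessel paths — a shadowed column carries no
  EZ signal, so truth under a vessel would be ill-defined, and the
  pipeline discards such detections by design;
* vessels: 3 smooth random-walk paths crossing the en face plane, 3 px
  wide, multiplying everything deeper than surface 4 by 0.45;
* speckle: multiplicative gamma noise, mean 1, σ = 0.2, applied last.

The default grid is 128×32×128 voxels over a 6×6 mm macular scan
(voxel 46.88 × 187.5 × 13.125 µm³), a 4×/4×/3.75× down-scaling of a native
512×128×480 acquisition chosen so that the full pipeline runs in ~40 s and
the complete test suite in ~1.5 min on one CPU.  Two consequences of that
scale are worth stating plainly.  First, lesions must survive the fixed
radius-5 morphological element, so their radii are 7–10 **pixels**
(en-face isotropic), which caps the intact:disrupted imbalance near 10:1
at this grid; the same physical lesion sizes on the native grid give
~80–100:1, the regime the method targets.  Second, the phantom's layers
are piecewise constant with stationary noise: passing tests demonstrate
the pipeline's correctness and internal consistency, not robustness to
real-scan pathology — motion artefacts, signal falloff, drusen-like
deformations, segmentation failure modes on low-quality scans, or
subjective ground-truth ambiguity at lesion margins all lie outside what
the phantom emulates.

## Numerical and design choices

* Surfaces are stored at sub-voxel precision; all voxel-membership
  rounding is `floor(z + 0.5)` (half toward the deeper surface).
* The surface-recovery oracle (speckle off, max error ≤ 1 voxel for all 11
  surfaces) runs on a lesion-free phantom with vessels: a lesion erases
  the surface-8 gradient, making sub-voxel recovery under it ill-posed.
* `run_all` derives every seed (cohort, per-fold under-sampling) from the
  master seed via `SeedSequence`; two runs with the same config are
  byte-identical, and every artifact embeds a SHA-256 config digest.
  Stage outputs are written once per run; no on-disk caching is performed
  (a full default run is ~40 s, so caching would add complexity without
  benefit).
* Volumes are stored as multipage TIFF (pages = B-scans) or NIfTI-1 with a
  JSON sidecar for the voxel size; intensities are never rescaled at I/O.
* Disruption volume keeps full floating-point precision
  (count × Δx·Δy·Δz × 10⁻⁹ mm³); no rounding convention is applied.

## Known limitations

* The surface search is per-B-scan; across-B-scan coherence comes only
  from the TPS smoothing, not from the optimization itself.
* The vessel detector is trained on phantom fixtures; on real scans it
  would need retraining on labelled projections, and the adaptive
  median-darkness gate is a heuristic.
* Normal-only cohorts cannot be used for leave-one-out training (no
  disrupted voxels); they require a pre-trained model, mirroring how a
  trained detector would be applied in screening.
* Metrics are voxel-level within the VOI; per-lesion (component-level)
  detection statistics are not computed.
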