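# Methods

This note documents the models and procedures implemented in `timescope`,
the assumptions behind them, the parameters that matter, and the design
choices made where the method description left the design open.

## Imaging model and calibration

Input videos are single-field-of-view grayscale RCM sequences. All physical
quantities derive from two calibrations carried on `VideoStack`: the frame
interval (default 0.2 s, i.e. 5 fps, so that 3/4/5-frame windows span
0.6/0.8/1.0 s) and the lateral pixel scale (default 1.33 px/µm; a 0.75 mm
field at ~1000 px). Conversions to micrometres are exact quotients;
*displayed* values are truncated (not rounded) to 2 decimals
(`px_to_um_display`), the convention that reproduces the reference
conversions 7.5 px → 5.63 µm and 20 px → 15.03 µm.

## Stabilization

Two-step, matching how handheld in vivo acquisition fails: large rigid
motion first, slow tissue deformation second.

1. **Linear pre-alignment.** SIFT keypoints per frame are matched to the
   first frame (cross-checked, ratio test 0.9) and a rigid transform
   (affine optional) is estimated by RANSAC (residual 2 px, ≥ 8 inliers
   required). Frames with < 4 matches or too small a consensus keep the
   identity with a logged warning — better an unstabilized frame than a
   hallucinated transform. Resampling pads with exactly 0, which defines
   "blank" for cropping.
2. **Auto-crop.** On the temporal-minimum image, the boundary line (top,
   bottom, left or right) with the most blank pixels is removed iteratively
   until every boundary line is at most 3/4 blank. Ties break in the fixed
   order top, bottom, left, right, making the rectangle deterministic. The
   crop refuses to shrink a dimension below 16 px (frames that already
   start smaller may shrink, but never to zero).
3. **Chained demons registration.** Frame t+1 is histogram-matched (256
   levels) to the already-stabilized frame t and registered onto it by
   multi-resolution demons (4 levels, shrink factor 2 per level, iterations
   [100, 50, 10, 1] coarse→fine, Gaussian field smoothing σ = 1). Chaining
   to the *transformed* predecessor propagates a consistent reference
   through the video; the non-diffeomorphic variant suffices because the
   residual motion after pre-alignment is small and smooth. A second crop
   pass removes regions not in view throughout.

The stabilization quality metric is the mean per-pixel temporal variance
(`residual_motion_score`). On synthetic videos it has an irreducible floor
from speckle and vessel flicker — both temporally independent — so
registration quality should be assessed on low-noise sequences or by the
*reduction* relative to input.

## Vessel segmentation

Assumption: after stabilization, areas of high frame-to-frame variation are
vessels (flowing blood), everything else is static. The temporal FIR
kernel (0.5, −1, 0.5) is a second difference: it annihilates any per-pixel
intensity trend linear in time (slow drift, bleaching) and responds to
flicker. Its absolute response is the per-pixel variation (the kernel is
sign-indefinite; variation is a magnitude). The 7×7 median suppresses
speckle-scale outliers; subtracting each frame's mean variation (clipping
negatives to 0) removes globally varying frames; accumulation is the *mean*
over frames so maps are comparable across video lengths. Otsu thresholding
assumes a bimodal map — a constant map has no threshold and yields an empty
mask with a warning. Size gates keep components with
`ceil(0.001·N) ≤ size ≤ floor(0.10·N)` pixels; the closing structuring
element is a disk of radius 3 px (exposed in config). Diameters are twice
the Euclidean distance transform sampled along the component skeleton — the
standard local-width estimate for tubular shapes.

## Trafficking

- **Background subtraction**: per-pixel median over a centered window of
  `round(6 s / frame_interval)` frames, truncated at the boundaries. A cell
  moving ≥ its own diameter per few frames occupies any one pixel for a
  small minority of a 6-s window, so the median ignores it; static texture
  cancels exactly.
- **Detection**: single-scale DoG at σ = radius/√2 with σ-ratio 1.6,
  response normalized so an ideal Gaussian blob of matched size and
  amplitude A scores quality ≈ A. "Quality" is therefore on the scale of
  background-subtracted blob amplitude; the 1.6 threshold is a calibration
  point of the synthetic generator's particle amplitude (2.5). Subpixel
  positions come from 1-D quadratic interpolation around each maximum.
- **Linking**: per frame pair, the exact minimum-cost assignment (scipy
  Hungarian solver on the standard augmented matrix) with squared-distance
  costs, links > 20 px forbidden, and a birth/death alternative cost of
  (1.05 · 20 px)². No gap closing, merging or splitting: a missed detection
  terminates a tracklet.
- **Filtering**: a tracklet survives window i if duration ≥ (0.6, 0.8,
  1.0 s)[i], displacement ≥ (20.5, 22.5, 22.5) px[i], mean absolute turning
  angle ≤ 58°, and mean quality ≥ (1.6, 1.65, 1.75)[i]. Duration is
  `n_detections · frame_interval` so 3/4/5-frame tracklets at 5 fps span
  exactly 0.6/0.8/1.0 s. Because every gate is at least as strict for
  longer windows, counts are monotone non-increasing from 0.6 s to 1.0 s.
  Counts are reported per video.

## Immune-cell segmentation

Three pixel classes: (1) dendritic cells and macrophages — elongated,
branched; (2) round-ellipsoid leukocyte-like cells; (3) background,
including all unlabeled pixels. The segmenter is a multiscale filter-bank
pixel classifier: per-pixel intensity, gradient and structure-tensor
texture features over Gaussian scales 0.5–8 px feed a one-hidden-layer MLP
trained by SGD with Nesterov momentum (learning rate 5e-2, batch 64,
90 epochs at the production defaults; log-loss). Shape information enters
through the texture features — tubes and blobs separate in
structure-tensor eigenvalue space. Training subsamples pixels per image,
oversampling the two rare cell classes (35/35/30%), since cells cover
~10% of a frame. Images are resampled to 256×256 (≈ 2 µm/px) bilinearly,
labels by nearest neighbour. With a fixed seed, training and prediction
are bit-deterministic. Evaluation is one-vs-rest Dice per class plus the
macro average; a class absent from both maps scores 1.

Tests and the acceptance script train at desk scale (128×128 inputs, 30
epochs, 20 training images, 3000 px/image) — sizes chosen so the complete
suite runs quickly on one CPU while still exercising the full training
path.

## Phenotyping (HCPC)

Grades are z-scored per feature (population SD; correlation-matrix PCA —
all features share the 0–3 scale). PCA retains the fewest leading
components explaining ≥ 95% of variance; component signs are fixed by
making each component's largest-magnitude loading positive. Ward-linkage
clustering runs on the retained scores; `n_clusters="auto"` picks k ∈ 2…6
maximizing the relative loss of within-cluster inertia between successive
partitions; an explicit k (e.g. 2 for small cohorts) is supported. An
optional k-means consolidation pass is off by default for reproducibility.

Axis naming: the vascular axis is the retained component where the summed
squared-loading contribution of the vascular features (vessel count,
dilated vessels, trafficking) is largest; the inflammation axis likewise
(intratumor/peritumor/perivascular inflammation); the two must differ,
otherwise an error asks for a manual override. Each axis is oriented so its
defining features' loadings sum positive, and a cluster is HIGH on an axis
when its centroid exceeds 0 (the grand mean) on the oriented axis. This
makes the qualitative naming reproducible. A caveat the test suite
documents: with exactly three clusters at the corners high-vasc/low-inflam,
low-vasc/high-inflam and high/high, the two feature blocks are negatively
correlated and the principal axes rotate toward cluster contrasts; the
high-vasc/low-inflam label is still recovered, but naming all corners
requires layouts (e.g. 2×2 factorial) in which the blocks are
decorrelated.

New samples project through the training standardization and loadings and
take the nearest centroid (Euclidean, ties to the lowest cluster index).

## Agreement statistics

Cohen's κ uses the standard marginal-product chance term. For
imaging-vs-histology comparisons, where feature prevalence is extreme and κ
degenerates, Gwet's chance-corrected coefficient is used with linear
ordinal weights w(i,j) = 1 − |i−j|/(K−1); with identity weights it reduces
exactly to unweighted AC1 (property-tested). The category set is declared
(default {0,1,2,3}), not inferred, so unobserved grades still enter K.
Binary collapse maps grade 0 → absent, ≥ 1 → present; the two-reader
average grade is the rounded (half-up) mean. Spearman correlation is
two-tailed with average ranks, backed by scipy.

## Response modeling

A linear probability model — OLS of the 0/1 response on the selected
grades, classifying at 0.5 — rather than logistic regression: with n ≈ 13
and quasi-separable features, maximum-likelihood logistic fits diverge,
while OLS stays defined and its AIC is comparable across feature sets. The
AIC convention is fixed at n·ln(RSS/n) + 2(p + 2), counting intercept and
error variance; under it, appending a useless predictor orthogonal to the
response and the other predictors raises AIC by exactly 2 (tested).
Singular designs raise an error naming the collinear columns (pivoted QR).
Out-of-bag metrics come from leave-one-out CV; folds whose training split
loses a class are skipped with a warning rather than failing, since tiny
cohorts make this reachable. Forward selection adds, per iteration, the
candidate maximizing out-of-bag specificity (ties: accuracy, then lower
AIC) or minimizing AIC (ties: accuracy); remaining ties keep the earliest
candidate, making selection deterministic. Linear separability of 1–2
feature subsets is decided exactly by LP feasibility of a strict separator;
the maximal margin, when separable, comes from a hard-margin linear SVM
(scipy ships no QP solver).

## Synthetic data: what it emulates, and what it does not

The video generator plants: static tissue texture (low-pass Gaussian
field); tubular vessels in disjoint horizontal bands (≈ 8% of the frame at
defaults) whose pixels get i.i.d. per-frame intensity jitter (SD 0.25) —
the flicker the vessel segmentation keys on; bright trafficking cells
(Gaussian blobs, radius 7.5 px, amplitude 2.5) advancing along vessel
centerlines at constant arc-length speed, with all cells in one vessel
flowing in the same direction from staggered offsets, as cells carried by
a common blood flow do; a bounded-random-walk global translation; a smooth
nonlinear warp, sinusoidally modulated in time; and multiplicative gamma
speckle (shape 1/contrast², unit mean, temporally independent) applied
last. Feature tables draw each lesion as its planted cluster mean plus
Gaussian noise, rounded and clipped to integer grades, with Bernoulli
response per cluster; `BCC_LIKE_CLUSTERS` is the default three-phenotype
layout.

Not emulated: optical sectioning and depth-dependent contrast, melanin and
collagen scattering, axial (z) motion, spatially correlated speckle,
partial-volume vessel boundaries, reader disagreement in grading, and
real class-imbalance/morphology overlap between immune-cell types. Passing
tests therefore demonstrate algorithmic correctness under the stated
generative assumptions — recovery of planted structure, formula
equivalence, threshold behaviour — not clinical performance on patient
videos.

## Numerical choices and degenerate inputs

- Blank pixels are exactly 0 (the resampling fill value); real zero-valued
  tissue pixels in float input are not expected after acquisition offset.
- Variation maps are clipped at 0 after mean subtraction.
- Otsu on a constant map → empty mask plus warning, not an error.
- Tracklet consistency skips zero-length steps; an all-stationary tracklet
  has consistency 0 (it is removed by the displacement gate anyway).
- An RSS numerically at 0 makes the AIC undefined and raises.
- Cluster renumbering is by order of first appearance, so partitions are
  stable (up to relabeling) under sample and feature permutations.
- In the auto-k inertia ratio, drops below 0.1% of total inertia are
  floored: integer grades collapse duplicate lesions, so within-cluster
  inertia can hit exactly zero at large k and a vanishing denominator
  would otherwise select a spurious fine partition.

## Problem sizes

Default test/acceptance scales: 256×256 × 50-frame videos for vessel
recovery, 20-frame videos with 6 planted cells for trafficking, 10-frame
low-noise videos for registration, 30-lesion tables for phenotyping, and
20+4 images at 128×128 for segmentation — chosen so the full suite and the
acceptance script each complete in well under a minute of compute per
stage on a single CPU.

## Known limitations

- The linear pre-alignment registers every frame to the first frame; a
  degraded first frame degrades the whole alignment (a configurable
  reference is a natural extension).
- Demons registration can absorb genuine biological motion (vessel
  pulsation) if iterated aggressively; the steep iteration schedule
  [100, 50, 10, 1] limits fine-scale warping.
- Detection quality is calibrated in blob-amplitude units; on real videos
  the threshold 1.6 must be recalibrated against manual counts, as any
  fixed detector threshold must.
- The auto-k inertia rule can be unstable on weakly separated tables;
  forcing k is supported and recommended for small cohorts.
- Per-vessel (rather than per-video) trafficking attribution and
  classification of trafficking sub-events (rolling vs adhesion vs
  crawling) are out of scope.
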