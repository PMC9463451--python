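# timescope

Quantification and phenotyping of the tumor immune microenvironment (TiME)
from in vivo reflectance confocal microscopy (RCM) of skin tumors.

RCM images skin at cellular resolution without labels, so immune cells,
blood vessels and leukocyte trafficking can be watched inside a patient's
tumor rather than inferred from a biopsy. This package implements the full
computational pipeline for turning those grayscale video sequences and
graded feature tables into quantitative TiME readouts, for imaging groups
working on non-invasive tumor characterization and treatment-response
prediction:

- **Video stabilization** — two steps: linear pre-alignment from matched
  scale-invariant keypoints (SIFT + RANSAC, rigid by default), automatic
  cropping of out-of-view borders (iteratively removing the boundary line
  with the most blank pixels in the temporal-minimum image until all four
  lines are ≤ 3/4 blank), then chained nonlinear demons registration
  (4 pyramid levels, iterations [100, 50, 10, 1], each frame
  histogram-matched to its stabilized predecessor).
- **Vessel segmentation** — flowing blood flickers while stabilized tissue
  does not. Per frame: Gaussian smoothing (σ = 1 px), a temporal FIR
  high-pass `F = (0.5, −1, 0.5)` whose absolute response is the per-pixel
  variation, a 7×7 spatial median, and subtraction of the frame-mean
  variation; the time-averaged map is Otsu-thresholded, morphologically
  closed, and size-gated (components < 0.1% or > 10% of the frame removed).
  Metrics: component count, area fraction, skeleton/distance-transform
  diameters in µm (1.33 px/µm).
- **Leukocyte trafficking** — rolling 6-s temporal-median background
  subtraction, difference-of-Gaussians spot detection (radius 7.5 px =
  5.63 µm, subpixel, quality ≥ 1.6), frame-to-frame linear-assignment
  linking (max 20 px = 15.03 µm, no gap closing/splitting/merging), and
  tracklet filtering per temporal window (0.6/0.8/1.0 s) on displacement
  ≥ [20.5, 22.5, 22.5] px, consistency ≤ 58°, quality ≥ [1.6, 1.65, 1.75].
- **Immune-cell segmentation** — 3-class pixelwise segmentation
  (dendritic/macrophage, round leukocyte-like, background) with derived
  inflammation area percentages.
- **Phenotyping** — hierarchical clustering on principal components (HCPC):
  z-scored 0–3 grades, PCA retaining ≥ 95% variance, Ward clustering, and
  Inflam^{HIGH|LOW} Vasc^{HIGH|LOW} naming from the components dominated by
  the inflammation and vasculature feature sets.
- **Agreement statistics** — Cohen's κ (two readers), Gwet's
  chance-corrected coefficient with linear ordinal weights
  (imaging vs histology), binary grade collapse, Spearman correlation.
- **Response modeling** — leave-one-out cross-validated linear probability
  models with greedy forward selection under specificity-first or
  AIC-first criteria (AIC = n·ln(RSS/n) + 2(p + 2)).

A first-class synthetic-data module generates RCM-like videos (flickering
tubular vessels, moving bright cells, drift, smooth deformation,
multiplicative speckle), immune label maps and graded feature tables with
known ground truth, so every stage is testable end to end.

## Worked example

```python
from timescope import (generate_rcm_video, variation_map, segment_vessels,
                       vessel_metrics, count_trafficking, dice_coefficient)

video, truth = generate_rcm_video(n_frames=30, n_vessels=2,
                                  n_trafficking_cells=4, seed=42)
vmap = variation_map(video)
mask = segment_vessels(vmap)
metrics = vessel_metrics(mask, video.pixel_per_um)
counts, _ = count_trafficking(video)
print(f"vessels: {metrics.n_vessels}  "
      f"area fraction: {metrics.area_fraction:.3f}")
print(f"mean diameters (um): "
      f"{[round(d[0], 1) for d in metrics.diameters_um]}")
print(f"dice vs planted mask: "
      f"{dice_coefficient(mask.mask, truth.vessel_mask):.3f}")
print(f"trafficking counts (0.6/0.8/1.0 s): {counts}")
```

prints

```
vessels: 2  area fraction: 0.078
mean diameters (um): [8.9, 8.9]
dice vs planted mask: 0.784
trafficking counts (0.6/0.8/1.0 s): (4, 4, 4)
```

Both planted vessels are found (Dice 0.78 against the planted mask, ~8% of
the frame vascularized, ~9 µm mean lumen diameter), and all four planted
trafficking cells are counted in every temporal window.

Phenotyping and response modeling follow the Model/Results convention:

```python
from timescope import PhenotypeModel, ResponseModel, generate_feature_table
from timescope.synthetic import BCC_LIKE_CLUSTERS

table, truth = generate_feature_table(30, BCC_LIKE_CLUSTERS, seed=0)
results = PhenotypeModel(table).fit(n_clusters="auto")
results.assign_phenotype_labels()
print(results.summary())

model = ResponseModel(table)
for fit in model.forward_select(results.model.feature_names, max_features=2):
    print(fit.summary())
```

A thin CLI wraps the same library: `time-scope simulate | stabilize |
vessels | trafficking | phenotype | respond | agreement | run`.

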