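"""End-to-end pipeline driver: videos in, per-lesion quantification out.

Per video: stabilization (two-step), vessel metrics from the temporal
variation map, trafficking counts per temporal window. If a graded feature
table is supplied the results merge with it, and phenotyping (HCPC) and,
when response labels are present, LOOCV response modeling run downstream.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import stabilization as stab
from . import trafficking as traf
from . import vessels as ves
from .config import PipelineConfig
from .phenotyping import PhenotypeModel
from .response import ResponseModel
from .video import VideoStack, read_video

logger = logging.getLogger(__name__)


def quantify_video(video: VideoStack, config: PipelineConfig) -> dict:
    """Stabilize one video and extract vessel and trafficking quantities."""
    row: dict = {"source_id": video.source_id}
    if config.stabilization.enabled:
        sc = config.stabilization
        result = stab.stabilize(video, transform_type=sc.transform_type,
                                pyramid_levels=sc.pyramid_levels,
                                iterations_per_level=list(sc.iterations_per_level))
        video = result.stabilized
        row["residual_motion_score"] = result.residual_motion_score
        logger.info("stabilized %s: crop_rect=%s residual=%.4g",
                    video.source_id, result.crop_rect,
                    result.residual_motion_score)
    if config.vessels.enabled:
        vc = config.vessels
        vmap = ves.variation_map(video, gaussian_sigma_px=vc.gaussian_sigma_px,
                                 fir_kernel=tuple(vc.fir_kernel),
                                 median_window_px=vc.median_window_px)
        mask = ves.segment_vessels(vmap, min_area_frac=vc.min_area_frac,
                                   max_area_frac=vc.max_area_frac,
                                   closing_radius_px=vc.closing_radius_px)
        metrics = ves.vessel_metrics(mask, video.pixel_per_um)
        row.update(n_vessels=metrics.n_vessels,
                   vessel_area_fraction=metrics.area_fraction,
                   vessel_mean_diameter_um=(
                       sum(d[0] for d in metrics.diameters_um)
                       / len(metrics.diameters_um)
                       if metrics.diameters_um else 0.0))
    if config.trafficking.enabled:
        tc = config.trafficking
        thresholds = traf.TraffickingThresholds(
            windows_s=tuple(tc.windows_s),
            windows_frames=tuple(range(3, 3 + len(tc.windows_s))),
            displacement_px=tuple(tc.displacement_px),
            displacement_um=tuple(p / video.pixel_per_um
                                  for p in tc.displacement_px),
            consistency_deg=tuple(tc.consistency_deg),
            quality=tuple(tc.quality))
        counts, _ = traf.count_trafficking(
            video, thresholds, radius_px=tc.radius_px,
            quality_threshold=tc.quality_threshold,
            max_link_px=tc.max_link_px,
            background_window_s=tc.background_window_s)
        for w, c in zip(tc.windows_s, counts):
            row[f"trafficking_count_{w:g}s"] = c
    return row


def run_pipeline(videos: list[VideoStack | str | Path],
                 feature_table: pd.DataFrame | str | Path | None = None,
                 config: PipelineConfig | None = None) -> dict:
    """Run the full analysis; returns a dict of result tables.

    ``quantification`` holds one row per video. With a feature table,
    ``phenotypes`` holds the fitted HCPC assignment per lesion, and — when
    the table carries a binary ``response`` column — ``response_models``
    holds forward-selection results.
    """
    config = config or PipelineConfig()
    logging.basicConfig(level=config.log_level)
    rows = []
    for v in videos:
        if not isinstance(v, VideoStack):
            path = Path(v)
            if not path.exists():
                raise FileNotFoundError(f"input video not found: {path}")
            v = read_video(path, frame_interval_s=config.frame_interval_s,
                           pixel_per_um=config.pixel_per_um)
        try:
            rows.append(quantify_video(v, config))
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed on video '{v.source_id}': {exc}") from exc
    out: dict = {"quantification": pd.DataFrame(rows)}

    if feature_table is not None:
        if not isinstance(feature_table, pd.DataFrame):
            feature_table = pd.read_csv(feature_table, index_col=0)
        if config.phenotyping.enabled:
            results = PhenotypeModel(feature_table).fit(
                n_clusters=config.phenotyping.n_clusters,
                variance_retained=config.phenotyping.variance_retained)
            try:
                results.assign_phenotype_labels()
            except ValueError:
                logger.warning("phenotype axis naming skipped (feature sets "
                               "do not separate on distinct components)")
            pheno = pd.DataFrame(
                {"cluster": results.cluster_of_sample},
                index=feature_table.index)
            if results.cluster_labels is not None:
                pheno["label"] = [results.cluster_labels[c]
                                  for c in results.cluster_of_sample]
            out["phenotypes"] = pheno
            out["phenotype_results"] = results
        if config.response.enabled and "response" in feature_table.columns:
            model = ResponseModel(feature_table)
            candidates = [c for c in feature_table.columns if c != "response"]
            out["response_models"] = model.forward_select(
                candidates, mode=config.response.mode,
                max_features=config.response.max_features,
                cutoff=config.response.cutoff)
    return out
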