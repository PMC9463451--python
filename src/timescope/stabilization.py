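"""Two-step motion removal for RCM videos.

In vivo RCM acquisition with a handheld probe suffers large lateral motion
plus slow tissue deformation. Stabilization proceeds in two steps:

1. a linear pre-alignment — scale-invariant keypoints (SIFT) matched between
   each frame and the first frame, a rigid (optionally affine) transform
   estimated by RANSAC — followed by automatic cropping of borders that left
   the field of view;
2. a chained nonlinear registration — each frame is histogram-matched to its
   already-stabilized predecessor and warped onto it by multi-resolution
   demons registration (four pyramid levels, iterations [100, 50, 10, 1]) —
   followed by a second cropping pass.

Blank pixels introduced by resampling are exactly 0 (the padding value),
which is what the cropping rule keys on.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import SimpleITK as sitk
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import AffineTransform, EuclideanTransform, warp

from .video import VideoStack

logger = logging.getLogger(__name__)

MIN_CROP_DIM = 16


@dataclasses.dataclass
class StabilizationResult:
    """Output of the full two-step stabilization."""

    stabilized: VideoStack
    linear_transforms: list[np.ndarray]  # 3x3 homogeneous, frame -> reference
    crop_rect: tuple[int, int, int, int]  # (row0, col0, height, width)
    residual_motion_score: float  # mean per-pixel temporal variance


def residual_motion_score(frames: np.ndarray) -> float:
    """Mean per-pixel temporal variance — the stabilization quality metric."""
    return float(np.var(frames, axis=0).mean())


def _estimate_transform(ref_kp, ref_desc, kp, desc, transform_type,
                        min_inliers: int = 8):
    """RANSAC transform from matched SIFT keypoints; None if unreliable."""
    matches = match_descriptors(ref_desc, desc, cross_check=True,
                                max_ratio=0.9)
    if len(matches) < 4:
        return None
    src = kp[matches[:, 1]][:, ::-1]  # (x, y) order for skimage transforms
    dst = ref_kp[matches[:, 0]][:, ::-1]
    tform_cls = EuclideanTransform if transform_type == "rigid" else AffineTransform
    try:
        model, inliers = ransac((src, dst), tform_cls, min_samples=3,
                                residual_threshold=2.0, max_trials=500,
                                rng=0)
    except Exception:
        return None
    if model is None or inliers is None or inliers.sum() < min_inliers:
        return None
    return model


def prealign_linear(video: VideoStack, transform_type: str = "rigid"
                    ) -> tuple[VideoStack, list[np.ndarray]]:
    """Register every frame to the first frame with a keypoint-based transform.

    Scale-invariant keypoints are detected per frame and matched to the first
    frame; a rigid (default) or affine transform is fitted by RANSAC. Frames
    where fewer than 4 keypoints match, or where the RANSAC consensus is too
    small, fall back to the identity with a logged warning. Out-of-view
    pixels are filled with 0.

    Returns the aligned video and the per-frame 3x3 homogeneous transforms
    (mapping frame coordinates onto the reference).
    """
    if transform_type not in ("rigid", "affine"):
        raise ValueError("transform_type must be 'rigid' or 'affine'")
    if video.n_frames < 2:
        raise ValueError("pre-alignment needs at least 2 frames")

    frames = video.frames
    lo, hi = frames.min(), frames.max()
    norm = (frames - lo) / (hi - lo) if hi > lo else np.zeros_like(frames)

    sift = SIFT()
    try:
        sift.detect_and_extract(norm[0])
        ref_kp, ref_desc = sift.keypoints.copy(), sift.descriptors.copy()
    except RuntimeError:
        ref_kp, ref_desc = None, None

    out = np.empty_like(frames)
    out[0] = frames[0]
    transforms = [np.eye(3)]
    for t in range(1, video.n_frames):
        model = None
        if ref_kp is not None and len(ref_kp) >= 4:
            try:
                sift.detect_and_extract(norm[t])
                model = _estimate_transform(ref_kp, ref_desc, sift.keypoints,
                                            sift.descriptors, transform_type)
            except RuntimeError:
                model = None
        if model is None:
            logger.warning("frame %d: fewer than 4 reliable keypoint matches; "
                           "identity fallback", t)
            out[t] = frames[t]
            transforms.append(np.eye(3))
        else:
            # warp pulls from the inverse map: frame -> reference uses model
            out[t] = warp(frames[t], model.inverse, cval=0.0,
                          preserve_range=True)
            transforms.append(model.params.copy())
    return video.with_frames(out), transforms


def auto_crop(video: VideoStack | np.ndarray,
              blank_fraction: float = 0.75) -> tuple[int, int, int, int]:
    """Crop rectangle containing only pixels in view throughout the video.

    Computes the temporal-minimum image (a pixel that was ever blank is blank
    there) and iteratively removes, among the four current boundary lines,
    the one with the most blank (exactly-zero) pixels, until every boundary
    line has a blank fraction at or below ``blank_fraction``. Ties are broken
    in the order top, bottom, left, right. Returns ``(row0, col0, height,
    width)`` in 0-based half-open pixel coordinates.
    """
    frames = video.frames if isinstance(video, VideoStack) else np.asarray(video)
    if frames.ndim == 2:
        frames = frames[None]
    tmin = frames.min(axis=0)
    blank = tmin == 0

    r0, c0 = 0, 0
    r1, c1 = blank.shape  # half-open
    # frames that start below the floor may still be cropped, but never to 0
    min_rows = MIN_CROP_DIM if r1 >= MIN_CROP_DIM else 1
    min_cols = MIN_CROP_DIM if c1 >= MIN_CROP_DIM else 1
    while True:
        lines = [
            ("top", blank[r0, c0:c1].sum(), c1 - c0),
            ("bottom", blank[r1 - 1, c0:c1].sum(), c1 - c0),
            ("left", blank[r0:r1, c0].sum(), r1 - r0),
            ("right", blank[r0:r1, c1 - 1].sum(), r1 - r0),
        ]
        if all(cnt <= blank_fraction * n for _, cnt, n in lines):
            break
        name = max(lines, key=lambda item: item[1])[0]
        if name == "top":
            r0 += 1
        elif name == "bottom":
            r1 -= 1
        elif name == "left":
            c0 += 1
        else:
            c1 -= 1
        if r1 - r0 < min_rows or c1 - c0 < min_cols:
            raise ValueError("auto_crop would reduce a dimension below "
                             f"{MIN_CROP_DIM} px; video too unstable")
    return (r0, c0, r1 - r0, c1 - c0)


def apply_crop(video: VideoStack, rect: tuple[int, int, int, int]) -> VideoStack:
    r0, c0, h, w = rect
    return video.with_frames(video.frames[:, r0:r0 + h, c0:c0 + w])


def _multiscale_demons(fixed: np.ndarray, moving: np.ndarray,
                       pyramid_levels: int,
                       iterations_per_level: list[int],
                       smoothing_sigma: float) -> sitk.Image:
    """Coarse-to-fine demons displacement field (moving -> fixed)."""
    fixed_img = sitk.GetImageFromArray(fixed.astype(np.float32))
    moving_img = sitk.GetImageFromArray(moving.astype(np.float32))

    field = None
    # level 0 is the coarsest (largest shrink factor)
    for level in range(pyramid_levels):
        shrink = 2 ** (pyramid_levels - 1 - level)
        iters = iterations_per_level[level]
        if shrink > 1:
            f_lvl = sitk.Shrink(fixed_img, [shrink, shrink])
            m_lvl = sitk.Shrink(moving_img, [shrink, shrink])
        else:
            f_lvl, m_lvl = fixed_img, moving_img
        demons = sitk.DemonsRegistrationFilter()
        demons.SetNumberOfIterations(max(int(iters), 1))
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(smoothing_sigma)
        if field is None:
            field = demons.Execute(f_lvl, m_lvl)
        else:
            field = sitk.Resample(field, f_lvl, sitk.Transform(),
                                  sitk.sitkLinear, 0.0,
                                  sitk.sitkVectorFloat64)
            field = demons.Execute(f_lvl, m_lvl, field)
    return sitk.Resample(field, fixed_img, sitk.Transform(), sitk.sitkLinear,
                         0.0, sitk.sitkVectorFloat64)


def _match_histogram(moving: np.ndarray, reference: np.ndarray,
                     levels: int = 256) -> np.ndarray:
    matcher = sitk.HistogramMatchingImageFilter()
    matcher.SetNumberOfHistogramLevels(levels)
    matcher.SetNumberOfMatchPoints(64)
    matcher.ThresholdAtMeanIntensityOn()
    out = matcher.Execute(sitk.GetImageFromArray(moving.astype(np.float32)),
                          sitk.GetImageFromArray(reference.astype(np.float32)))
    return sitk.GetArrayFromImage(out).astype(np.float64)


def stabilize_nonlinear(video: VideoStack, pyramid_levels: int = 4,
                        iterations_per_level: list[int] | None = None,
                        smoothing_sigma: float = 1.0,
                        recrop: bool = True) -> StabilizationResult:
    """Chained demons registration removing slow tissue deformation.

    Frame t+1 is histogram-matched (256 levels) to frame t, then registered
    onto the *already transformed* frame t by multi-resolution demons with
    ``pyramid_levels`` levels and ``iterations_per_level`` iterations, coarse
    to fine; frame t+2 then registers to the transformed t+1, and so on. A
    second cropping pass removes any region not in view throughout. Expects a
    linearly pre-aligned, cropped video; a single-frame video is returned
    unchanged.
    """
    if iterations_per_level is None:
        iterations_per_level = [100, 50, 10, 1]
    if len(iterations_per_level) != pyramid_levels:
        raise ValueError("need one iteration count per pyramid level")
    if video.n_frames == 1:
        return StabilizationResult(
            stabilized=video, linear_transforms=[np.eye(3)],
            crop_rect=(0, 0, video.frames.shape[1], video.frames.shape[2]),
            residual_motion_score=0.0)

    frames = video.frames
    out = np.empty_like(frames)
    out[0] = frames[0]
    for t in range(1, video.n_frames):
        matched = _match_histogram(frames[t], out[t - 1])
        field = _multiscale_demons(out[t - 1], matched, pyramid_levels,
                                   iterations_per_level, smoothing_sigma)
        warped = sitk.Resample(
            sitk.GetImageFromArray(matched.astype(np.float32)),
            sitk.GetImageFromArray(out[t - 1].astype(np.float32)),
            sitk.DisplacementFieldTransform(field),
            sitk.sitkLinear, 0.0)
        out[t] = sitk.GetArrayFromImage(warped).astype(np.float64)

    result = video.with_frames(out)
    if recrop:
        rect = auto_crop(result)
        result = apply_crop(result, rect)
    else:
        rect = (0, 0, out.shape[1], out.shape[2])
    return StabilizationResult(
        stabilized=result,
        linear_transforms=[np.eye(3)] * video.n_frames,
        crop_rect=rect,
        residual_motion_score=residual_motion_score(result.frames))


def stabilize(video: VideoStack, transform_type: str = "rigid",
              pyramid_levels: int = 4,
              iterations_per_level: list[int] | None = None) -> StabilizationResult:
    """Full two-step stabilization: linear pre-alignment, crop, demons, crop."""
    aligned, transforms = prealign_linear(video, transform_type=transform_type)
    rect = auto_crop(aligned)
    cropped = apply_crop(aligned, rect)
    result = stabilize_nonlinear(cropped, pyramid_levels=pyramid_levels,
                                 iterations_per_level=iterations_per_level)
    # compose the two crop rectangles into original-frame coordinates
    r0, c0, _, _ = rect
    r1, c1, h, w = result.crop_rect
    return StabilizationResult(
        stabilized=result.stabilized,
        linear_transforms=transforms,
        crop_rect=(r0 + r1, c0 + c1, h, w),
        residual_motion_score=result.residual_motion_score)
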