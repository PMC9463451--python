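"""Temporal-variation blood-vessel segmentation and vessel metrics.

Flowing blood produces rapid frame-to-frame intensity fluctuation inside
vessel lumina while the surrounding (stabilized) tissue stays static, so
areas of high temporal variation between consecutive frames mark vessels.
The variation map is built per frame by Gaussian smoothing (sigma 1 px), a
temporal FIR high-pass with kernel (0.5, -1, 0.5) whose absolute response is
the per-pixel variation, 7x7 spatial median filtering, and subtraction of
each frame's mean variation (slowly varying areas drop out); the per-frame
maps are averaged into a single map, which is Otsu-thresholded,
morphologically closed and size-gated (components below 0.1% or above 10%
of the frame are removed) to yield the vessel mask.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk, skeletonize

from .video import VideoStack

logger = logging.getLogger(__name__)

FIR_KERNEL = (0.5, -1.0, 0.5)


@dataclasses.dataclass
class VariationMap:
    """Accumulated temporal-variation map of a stabilized video."""

    values: np.ndarray  # H x W, non-negative
    n_frames_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0 or not np.all(np.isfinite(self.values)):
            raise ValueError("variation map must be non-negative and finite")


@dataclasses.dataclass
class VesselMask:
    """Binary vessel map; components are counted with 8-connectivity."""

    mask: np.ndarray
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclasses.dataclass
class VesselMetrics:
    n_vessels: int
    area_fraction: float
    diameters_um: list[tuple[float, float]]  # per-component (mean, max)


def variation_map(video: VideoStack, gaussian_sigma_px: float = 1.0,
                  fir_kernel: tuple[float, float, float] = FIR_KERNEL,
                  median_window_px: int = 7) -> VariationMap:
    """Accumulate frame-to-frame variation over the whole video.

    Requires at least 3 frames (the FIR spans 3 consecutive frames). The
    kernel (0.5, -1, 0.5) is a second difference: any per-pixel intensity
    ramp that is linear in time is annihilated, so only genuine flicker
    survives.
    """
    if video.n_frames < 3:
        raise ValueError("variation_map needs at least 3 frames")
    smoothed = np.stack([ndimage.gaussian_filter(f, gaussian_sigma_px)
                         for f in video.frames])
    k = np.asarray(fir_kernel, dtype=float)
    # temporal convolution, valid region only: T-2 variation frames
    fir = (k[0] * smoothed[:-2] + k[1] * smoothed[1:-1] + k[2] * smoothed[2:])
    variation = np.abs(fir)
    accum = np.zeros(video.frames.shape[1:])
    for v in variation:
        v = ndimage.median_filter(v, size=median_window_px)
        v = np.clip(v - v.mean(), 0.0, None)
        accum += v
    accum /= len(variation)
    return VariationMap(values=accum, n_frames_used=video.n_frames)


def segment_vessels(vmap: VariationMap, min_area_frac: float = 0.001,
                    max_area_frac: float = 0.10,
                    closing_radius_px: int = 3) -> VesselMask:
    """Otsu threshold, morphological closing and size gating of a variation map.

    Components smaller than 0.1% or larger than 10% of the frame (defaults)
    are removed: a component of ``size`` pixels is kept when
    ``ceil(min_area_frac * N) <= size <= floor(max_area_frac * N)``.
    A degenerate all-equal map yields an empty mask with a warning.
    """
    values = vmap.values
    if np.ptp(values) == 0:
        logger.warning("variation map is constant; no Otsu threshold exists "
                       "- returning empty mask")
        return VesselMask(mask=np.zeros_like(values, dtype=bool))
    thr = threshold_otsu(values)
    binary = values > thr
    binary = ndimage.binary_closing(binary, structure=disk(closing_radius_px))
    n_px = values.size
    lo = math.ceil(min_area_frac * n_px)
    hi = math.floor(max_area_frac * n_px)
    labeled, n = label(binary, connectivity=2, return_num=True)
    out = np.zeros_like(binary)
    for i in range(1, n + 1):
        comp = labeled == i
        if lo <= comp.sum() <= hi:
            out |= comp
    return VesselMask(mask=out)


def vessel_metrics(mask: VesselMask, pixel_per_um: float) -> VesselMetrics:
    """Component count, area fraction and per-component diameters.

    Diameters are measured as twice the Euclidean distance-transform value
    sampled along each component's morphological skeleton, converted to
    micrometres; (mean, max) is reported per component.
    """
    m = mask.mask
    labeled, n = label(m, connectivity=2, return_num=True)
    area_fraction = float(m.sum()) / m.size if m.size else 0.0
    dist = ndimage.distance_transform_edt(m)
    diameters: list[tuple[float, float]] = []
    for i in range(1, n + 1):
        comp = labeled == i
        skel = skeletonize(comp)
        samples = 2.0 * dist[skel] if skel.any() else 2.0 * dist[comp]
        diameters.append((float(samples.mean() / pixel_per_um),
                          float(samples.max() / pixel_per_um)))
    return VesselMetrics(n_vessels=n, area_fraction=area_fraction,
                         diameters_um=diameters)


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
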