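"""Synthetic RCM-like data with known ground truth.

Every downstream stage of the pipeline (stabilization, vessel segmentation,
trafficking counting, immune-cell segmentation, phenotyping, response
modeling) is exercised against data produced here, so the generators plant
explicit ground truth:

* videos with tubular vessel regions whose intensity fluctuates frame to
  frame, bright round cells trafficking along vessel centerlines, static
  tissue texture, multiplicative speckle, bounded global drift and a smooth
  nonlinear warp;
* single frames with three pixel classes (dendritic/macrophage-like branched
  shapes, round-ellipsoid leukocyte-like cells, textured background);
* ordinal 0-3 feature tables with planted cluster structure and response
  labels enriched in chosen clusters.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .video import DEFAULT_PIXEL_PER_UM, VideoStack

#: Canonical ordinal TiME features graded 0-3 per lesion.
CANONICAL_FEATURES = (
    "number_of_vessels",
    "dilated_vessels",
    "trafficking",
    "intratumor_inflammation",
    "peritumor_inflammation",
    "perivascular_inflammation",
)

#: Default planted phenotype structure for a BCC-like cohort: three clusters
#: (vascular-high/inflammation-low, vascular-low/inflammation-high, high on
#: both), with vascular grade patterns strong enough that the vascular
#: features dominate the first principal component and the inflammation
#: features the second, and with response enriched in the
#: inflammation-high/vascular-low cluster.
BCC_LIKE_CLUSTERS = [
    ((3, 3, 3, 0, 1, 0), 10, 0.2),  # Inflam^LOW  Vasc^HIGH
    ((0, 1, 0, 3, 2, 3), 10, 0.8),  # Inflam^HIGH Vasc^LOW
    ((3, 2, 3, 3, 3, 2), 10, 0.5),  # Inflam^HIGH Vasc^HIGH
]


@dataclasses.dataclass
class SyntheticVideoTruth:
    """Planted structure of a synthetic RCM video.

    ``particle_tracks`` holds one array per trafficking cell with rows
    ``(frame_index, x, y)``; positions include the applied global drift but
    not the nonlinear warp (whose per-frame maximum magnitude is recorded in
    ``applied_deformation``).
    """

    vessel_mask: np.ndarray
    particle_tracks: list[np.ndarray]
    applied_drift: np.ndarray  # (T, 2) per-frame (dy, dx) in px
    applied_deformation: np.ndarray  # (T,) max displacement magnitude in px


@dataclasses.dataclass
class SyntheticTableTruth:
    """Planted cluster structure of a synthetic feature table."""

    cluster_of_sample: np.ndarray
    cluster_means: np.ndarray  # clusters x features, grades in [0, 3]
    response_prob_by_cluster: np.ndarray


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Zero-mean unit-SD Gaussian random field, low-pass filtered."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def _vessel_centerline(rng: np.random.Generator, width: int, y_center: float,
                       y_halfspan: float, n_points: int = 2048) -> np.ndarray:
    """Smooth left-to-right curve, columns (x, y), confined to a band."""
    x = np.linspace(2.0, width - 3.0, n_points)
    y = np.full(n_points, y_center)
    # two low-frequency sinusoids keep the path tubular and band-confined
    for harmonic in (1, 2):
        amp = rng.uniform(0.2, 0.45) * y_halfspan / harmonic
        phase = rng.uniform(0, 2 * np.pi)
        y = y + amp * np.sin(2 * np.pi * harmonic * x / width + phase)
    return np.column_stack([x, y])


def _stamp_tube(mask: np.ndarray, centerline: np.ndarray, radius: float) -> None:
    """Mark all pixels within ``radius`` of the polyline as vessel."""
    h, w = mask.shape
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (yy ** 2 + xx ** 2) <= radius ** 2
    for px, py in centerline[::2]:
        cx, cy = int(round(px)), int(round(py))
        y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
        x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
        mask[y0:y1, x0:x1] |= disk[y0 - (cy - r):y1 - (cy - r),
                                   x0 - (cx - r):x1 - (cx - r)]


def _arc_length_interp(centerline: np.ndarray) -> tuple[np.ndarray, float]:
    """Cumulative arc length per centerline sample and the total length."""
    steps = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    return s, float(s[-1])


def _gaussian_blob(shape: tuple[int, int], x: float, y: float, sigma: float,
                   amplitude: float) -> np.ndarray:
    """Isotropic Gaussian spot rendered on a local patch for speed."""
    h, w = shape
    out = np.zeros(shape)
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    if y0 >= y1 or x0 >= x1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    out[y0:y1, x0:x1] = amplitude * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma ** 2))
    return out


def generate_rcm_video(
    width_px: int = 256,
    height_px: int = 256,
    n_frames: int = 50,
    frame_interval_s: float = 0.2,
    n_vessels: int = 2,
    n_trafficking_cells: int = 0,
    particle_speed_px_per_frame: float = 6.0,
    drift_amplitude_px: float = 0.0,
    deformation_amplitude_px: float = 0.0,
    speckle_contrast: float = 0.2,
    seed: int = 0,
    vessel_radius_px: float = 5.0,
    vessel_flicker_sd: float = 0.25,
    particle_amplitude: float = 2.5,
    particle_radius_px: float = 7.5,
    pixel_per_um: float = DEFAULT_PIXEL_PER_UM,
) -> tuple[VideoStack, SyntheticVideoTruth]:
    """Render a synthetic RCM video with planted vessels and trafficking cells.

    Vessels are smooth tubular paths confined to disjoint horizontal bands
    (so ``n_vessels`` equals the number of connected components of the truth
    mask); at the default geometry (two vessels of radius 5 px spanning a
    256-px frame) the planted mask covers ~8% of the frame, typical of a
    vascular tumor field. Vessel pixels receive i.i.d. per-frame intensity jitter on top of
    the static tissue background, which is what the temporal-variation vessel
    segmentation keys on. Trafficking cells are bright Gaussian spots of
    radius ``particle_radius_px`` advancing along a vessel centerline at a
    constant arc-length speed, reflecting at the ends. A bounded-random-walk
    global translation and a smooth, temporally modulated nonlinear warp are
    applied by resampling with zero padding; multiplicative gamma speckle
    (shape ``1/speckle_contrast**2``, unit mean) is applied last.

    Returns the video and a :class:`SyntheticVideoTruth` recording all
    planted structure.
    """
    if width_px < 64 or height_px < 64:
        raise ValueError("frame dimensions must be at least 64 px")
    if n_frames < 2:
        raise ValueError("a video needs at least 2 frames")
    if min(drift_amplitude_px, deformation_amplitude_px, speckle_contrast) < 0:
        raise ValueError("amplitudes must be non-negative")
    if n_trafficking_cells > 0 and n_vessels == 0:
        raise ValueError("trafficking cells need at least one vessel path")

    rng = np.random.default_rng(seed)
    h, w = height_px, width_px

    # static tissue texture
    background = 0.5 + 0.1 * _smooth_noise(rng, (h, w), sigma=6.0)

    # vessels in disjoint horizontal bands
    vessel_mask = np.zeros((h, w), dtype=bool)
    centerlines: list[np.ndarray] = []
    if n_vessels > 0:
        band = h / n_vessels
        if band < 4 * vessel_radius_px + 8:
            raise ValueError("too many vessels for the frame height")
        for i in range(n_vessels):
            y_center = band * (i + 0.5)
            halfspan = band / 2 - vessel_radius_px - 3
            cl = _vessel_centerline(rng, w, y_center, halfspan)
            centerlines.append(cl)
            _stamp_tube(vessel_mask, cl, vessel_radius_px)

    # trafficking cells advance at constant arc-length speed. Cells are
    # dealt round-robin onto vessels; all cells in one vessel flow in the
    # same direction (carried by the same blood flow) from staggered start
    # offsets, so planted events stay resolvable at the detection scale.
    # Paths too short for the full travel reflect at the ends.
    particle_sigma = particle_radius_px / np.sqrt(2.0)
    per_vessel: list[list[int]] = [[] for _ in centerlines]
    for c in range(n_trafficking_cells):
        per_vessel[c % len(centerlines)].append(c)
    tracks_by_cell: dict[int, np.ndarray] = {}
    for vi, cell_ids in enumerate(per_vessel):
        if not cell_ids:
            continue
        cl = centerlines[vi]
        s, total = _arc_length_interp(cl)
        direction = 1.0 if rng.random() < 0.5 else -1.0
        travel = particle_speed_px_per_frame * (n_frames - 1)
        usable = max(total - travel, 0.0)
        k = len(cell_ids)
        for j, cid in enumerate(cell_ids):
            slot = (j + rng.uniform(0.25, 0.75)) / k
            s0 = slot * (usable if usable > 0 else total)
            if direction < 0:
                s0 = total - s0
            rows = []
            for t in range(n_frames):
                pos = s0 + direction * particle_speed_px_per_frame * t
                # reflect into [0, total] (triangle wave)
                pos = np.abs((pos + total) % (2 * total) - total)
                x = np.interp(pos, s, cl[:, 0])
                y = np.interp(pos, s, cl[:, 1])
                rows.append((t, x, y))
            tracks_by_cell[cid] = np.array(rows)
    tracks = [tracks_by_cell[c] for c in range(n_trafficking_cells)]

    # bounded random-walk drift
    drift = np.zeros((n_frames, 2))
    if drift_amplitude_px > 0:
        steps = rng.normal(0.0, drift_amplitude_px / 3.0, size=(n_frames, 2))
        steps[0] = 0.0
        drift = np.clip(np.cumsum(steps, axis=0),
                        -drift_amplitude_px, drift_amplitude_px)

    # smooth warp field, fixed shape, sinusoidally modulated in time
    deform_mag = np.zeros(n_frames)
    if deformation_amplitude_px > 0:
        dy_field = _smooth_noise(rng, (h, w), sigma=w / 6)
        dx_field = _smooth_noise(rng, (h, w), sigma=w / 6)
        norm = np.sqrt(dy_field ** 2 + dx_field ** 2).max()
        dy_field /= norm
        dx_field /= norm
        modulation = np.sin(2 * np.pi * np.arange(n_frames) / n_frames)
    grid_y, grid_x = np.mgrid[0:h, 0:w].astype(float)

    frames = np.empty((n_frames, h, w))
    shape_k = 1.0 / speckle_contrast ** 2 if speckle_contrast > 0 else None
    for t in range(n_frames):
        frame = background.copy()
        jitter = rng.normal(0.0, vessel_flicker_sd, size=int(vessel_mask.sum()))
        frame[vessel_mask] = np.clip(frame[vessel_mask] + jitter, 0.0, None)
        for track in tracks:
            _, x, y = track[t]
            frame += _gaussian_blob((h, w), x, y, particle_sigma,
                                    particle_amplitude)
        if drift_amplitude_px > 0:
            frame = ndimage.shift(frame, drift[t], order=1, cval=0.0)
        if deformation_amplitude_px > 0:
            scale = deformation_amplitude_px * modulation[t]
            deform_mag[t] = abs(scale)
            frame = ndimage.map_coordinates(
                frame, [grid_y + scale * dy_field, grid_x + scale * dx_field],
                order=1, cval=0.0)
        if shape_k is not None:
            frame = frame * rng.gamma(shape_k, 1.0 / shape_k, size=(h, w))
        frames[t] = frame

    # truth positions include drift (clipped to the frame)
    tracks_out = []
    for track in tracks:
        shifted = track.copy()
        shifted[:, 1] = np.clip(track[:, 1] + drift[:, 1], 0, w - 1)
        shifted[:, 2] = np.clip(track[:, 2] + drift[:, 0], 0, h - 1)
        tracks_out.append(shifted)

    video = VideoStack(frames=frames, frame_interval_s=frame_interval_s,
                       pixel_per_um=pixel_per_um, source_id=f"synthetic-{seed}")
    truth = SyntheticVideoTruth(vessel_mask=vessel_mask,
                                particle_tracks=tracks_out,
                                applied_drift=drift,
                                applied_deformation=deform_mag)
    return video, truth


def _branched_shape(rng: np.random.Generator, h: int, w: int,
                    cy: float, cx: float, n_branches: int = 3,
                    branch_len: int = 18) -> np.ndarray:
    """Elongated branched footprint (dendrite/macrophage-like), boolean map."""
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_branches):
        angle = rng.uniform(0, 2 * np.pi)
        y, x = cy, cx
        for _ in range(branch_len):
            angle += rng.normal(0, 0.3)
            y += np.sin(angle)
            x += np.cos(angle)
            iy, ix = int(round(y)), int(round(x))
            if 1 <= iy < h - 1 and 1 <= ix < w - 1:
                mask[iy - 1:iy + 2, ix - 1:ix + 2] = True
    return mask


def generate_immune_labelmap(
    width_px: int = 256,
    height_px: int = 256,
    n_round_cells: int = 10,
    n_dendritic_cells: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic RCM frame with a 3-class pixel label map.

    Class 1: elongated branched dendritic/macrophage-like shapes; class 2:
    round-ellipsoid leukocyte-like cells (exactly ``n_round_cells`` connected
    components); class 3: textured background. Object placements are
    rejection-sampled so no two objects touch.
    """
    if n_round_cells < 0 or n_dendritic_cells < 0:
        raise ValueError("cell counts must be non-negative")
    rng = np.random.default_rng(seed)
    h, w = height_px, width_px
    labels = np.full((h, w), 3, dtype=np.uint8)
    occupied = np.zeros((h, w), dtype=bool)
    image = 0.3 + 0.05 * _smooth_noise(rng, (h, w), sigma=3.0)

    margin = min(25, h // 5, w // 5)

    def place(footprint_fn, label_value, brightness):
        for _ in range(200):  # rejection sampling
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            fp = footprint_fn(cy, cx)
            if not fp.any():
                continue
            if not (ndimage.binary_dilation(fp, iterations=3) & occupied).any():
                labels[fp] = label_value
                occupied[fp] = True
                image[fp] = brightness + rng.normal(0, 0.03, int(fp.sum()))
                return True
        return False

    yy, xx = np.mgrid[0:h, 0:w]

    def round_cell(cy, cx):
        a = rng.uniform(4.0, 7.0)
        b = a * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def dendritic(cy, cx):
        return _branched_shape(rng, h, w, cy, cx)

    for _ in range(n_round_cells):
        if not place(round_cell, 2, brightness=0.95):
            raise RuntimeError("could not place all round cells; frame too small")
    for _ in range(n_dendritic_cells):
        if not place(dendritic, 1, brightness=0.75):
            raise RuntimeError("could not place all dendritic cells")

    image = ndimage.gaussian_filter(image, 0.8)
    image += rng.normal(0, 0.02, size=(h, w))
    return image, labels


def generate_feature_table(
    n_samples: int,
    cluster_spec: list[tuple],
    noise_sd: float = 0.3,
    seed: int = 0,
    feature_names: tuple[str, ...] = CANONICAL_FEATURES,
    with_response: bool = True,
) -> tuple[pd.DataFrame, SyntheticTableTruth]:
    """Ordinal 0-3 feature table with planted clusters and response labels.

    ``cluster_spec`` is a list of ``(mean_vector, n_in_cluster,
    response_prob)`` triples; cluster sizes must sum to ``n_samples`` and
    means must lie in [0, 3]. Each row is its cluster mean plus Gaussian
    noise, rounded and clipped to integer grades in {0, 1, 2, 3}; the binary
    response is Bernoulli per cluster.
    """
    sizes = [n for _, n, _ in cluster_spec]
    if sum(sizes) != n_samples:
        raise ValueError("cluster sizes must sum to n_samples")
    means = np.array([np.asarray(m, dtype=float) for m, _, _ in cluster_spec])
    if means.shape[1] != len(feature_names):
        raise ValueError("cluster mean length must match feature_names")
    if means.min() < 0 or means.max() > 3:
        raise ValueError("cluster means must lie in [0, 3]")
    probs = np.array([p for _, _, p in cluster_spec], dtype=float)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("response probabilities must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    rows, resp, member = [], [], []
    for k, (mean, n_k, p_k) in enumerate(zip(means, sizes, probs)):
        noisy = mean + rng.normal(0.0, noise_sd, size=(n_k, len(mean)))
        rows.append(np.clip(np.rint(noisy), 0, 3).astype(int))
        resp.append((rng.random(n_k) < p_k).astype(int))
        member.append(np.full(n_k, k))
    grades = np.vstack(rows)
    table = pd.DataFrame(grades, columns=list(feature_names))
    table.index = [f"lesion_{i:03d}" for i in range(n_samples)]
    table.index.name = "sample_id"
    if with_response:
        table["response"] = np.concatenate(resp)
    truth = SyntheticTableTruth(cluster_of_sample=np.concatenate(member),
                                cluster_means=means,
                                response_prob_by_cluster=probs)
    return table, truth
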