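"""Video container and TIFF I/O for reflectance confocal microscopy sequences.

RCM videos are single-field-of-view grayscale image sequences. The container
carries the two physical calibrations every downstream stage needs: the frame
interval in seconds and the lateral pixel scale in pixels per micrometre
(1.33 px/um for the instrument this pipeline targets, i.e. a 0.75 x 0.75 mm
field imaged at ~1000 x 1000 px).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile

#: Lateral scale of the targeted RCM instrument, pixels per micrometre.
DEFAULT_PIXEL_PER_UM = 1.33


@dataclasses.dataclass
class VideoStack:
    """A T x H x W grayscale video with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity frames, any real dtype; converted to float64 on validation.
    frame_interval_s : float
        Time between consecutive frames in seconds.
    pixel_per_um : float
        Lateral pixel scale (pixels per micrometre).
    source_id : str
        Free-text provenance tag (file name, lesion id, ...).
    """

    frames: np.ndarray
    frame_interval_s: float = 0.2
    pixel_per_um: float = DEFAULT_PIXEL_PER_UM
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        t, h, w = self.frames.shape
        if t < 1:
            raise ValueError("video must contain at least one frame")
        if h < 16 or w < 16:
            raise ValueError(f"frames must be at least 16 x 16 px, got {h} x {w}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite intensities")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_per_um <= 0:
            raise ValueError("pixel_per_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def with_frames(self, frames: np.ndarray) -> "VideoStack":
        """Return a copy of this stack carrying new frame data."""
        return VideoStack(
            frames=frames,
            frame_interval_s=self.frame_interval_s,
            pixel_per_um=self.pixel_per_um,
            source_id=self.source_id,
        )


def read_video(path: str | Path, frame_interval_s: float = 0.2,
               pixel_per_um: float = DEFAULT_PIXEL_PER_UM) -> VideoStack:
    """Read a multi-page TIFF / OME-TIFF into a :class:`VideoStack`."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return VideoStack(frames=arr, frame_interval_s=frame_interval_s,
                      pixel_per_um=pixel_per_um, source_id=path.name)


def write_video(video: VideoStack, path: str | Path) -> None:
    """Write a stack as a 32-bit float multi-page TIFF."""
    tifffile.imwrite(Path(path), video.frames.astype(np.float32))
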