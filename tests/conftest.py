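"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from timescope import generate_feature_table, generate_rcm_video
from timescope.synthetic import BCC_LIKE_CLUSTERS


@pytest.fixture(scope="session")
def vessel_video():
    """Default-geometry flickering-vessel video with its planted truth."""
    return generate_rcm_video(n_frames=50, n_vessels=2,
                              n_trafficking_cells=0, seed=1)


@pytest.fixture(scope="session")
def trafficking_video():
    """Six planted cells moving 6 px/frame along two vessels, low noise."""
    return generate_rcm_video(n_frames=20, n_vessels=2,
                              n_trafficking_cells=6,
                              particle_speed_px_per_frame=6.0, seed=3)


@pytest.fixture(scope="session")
def bcc_table():
    """30-lesion table with three planted BCC-like phenotype clusters."""
    return generate_feature_table(30, BCC_LIKE_CLUSTERS, noise_sd=0.25, seed=0)


@pytest.fixture(scope="session")
def static_video():
    """A video whose frames are all identical (no motion, no noise)."""
    video, _ = generate_rcm_video(n_frames=2, n_vessels=2,
                                  speckle_contrast=0.0, seed=5)
    return video.with_frames(np.repeat(video.frames[:1], 6, axis=0))
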