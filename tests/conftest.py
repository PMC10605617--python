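"""Shared fixtures: synthetic scenes and movies reused across test modules.

Heavier simulations are session-scoped so the suite renders each movie
once; tests must not mutate fixture contents.
"""

from __future__ import annotations

import numpy as np
import pytest

from ulmvasc import (
    AcquisitionParams,
    TrackerParams,
    generate_vessel_tree,
    simulate_mb_movie,
)
from ulmvasc.detection import detect_stack
from ulmvasc.motion import correct_positions, estimate_motion
from ulmvasc.tracking import track_microbubbles


@pytest.fixture(scope="session")
def default_tree():
    """Straight-vesseled tree covering all three anatomical bands."""
    return generate_vessel_tree(
        n_root_vessels=8, branching_depth=2, tortuosity_amp=0.0, dims=2, seed=3
    )


@pytest.fixture(scope="session")
def default_movie(default_tree):
    """Low-density movie (few concurrent bubbles, SNR >> 10) with motion."""
    acq = AcquisitionParams(n_frames=110, seed=5)
    contrast, bmode, truth = simulate_mb_movie(default_tree, acq)
    return contrast, bmode, truth, acq


@pytest.fixture(scope="session")
def tracked_movie(default_movie):
    """The default movie pushed through detect -> motion -> correct -> track."""
    contrast, bmode, truth, acq = default_movie
    dets = detect_stack(contrast)
    motion = estimate_motion(bmode)
    corrected = correct_positions(dets, motion)
    tracks = track_microbubbles(corrected, TrackerParams(), acq.frame_rate)
    return tracks, corrected, motion, truth, acq


def gaussian_blob_frame(
    shape: tuple[int, int], center_mm: tuple[float, float], pixel_size: float,
    sigma_mm: float = 0.15, amplitude: float = 1.0
) -> np.ndarray:
    """Noiseless frame holding one Gaussian blob at a sub-pixel position."""
    zz, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx = center_mm[0] / pixel_size - 0.5
    cz = center_mm[1] / pixel_size - 0.5
    s = sigma_mm / pixel_size
    return amplitude * np.exp(-((zz - cz) ** 2 + (xx - cx) ** 2) / (2 * s**2))
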