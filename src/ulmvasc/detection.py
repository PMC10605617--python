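"""Microbubble detection and sub-pixel localization on contrast frames."""

from __future__ import annotations

import numpy as np
from skimage.feature import peak_local_max

from .datatypes import Detection, FrameStack

__all__ = ["detect_microbubbles", "detect_stack"]


def detect_microbubbles(
    frame: np.ndarray,
    pixel_size: float,
    frame_index: int = 0,
    rel_threshold: float = 0.3,
    min_separation: float | None = None,
    window_px: int = 5,
    abs_threshold: float | None = None,
) -> list[Detection]:
    """Detect isolated microbubbles in one contrast frame.

    Local maxima above ``rel_threshold`` x the frame maximum are kept, with
    non-maximum suppression over ``min_separation`` (mm, default one PSF
    width of 2 pixels), then refined to sub-pixel precision by an
    intensity-weighted centroid over a ``window_px`` x ``window_px``
    neighbourhood.  Positions are (x, z) in mm of the pixel-centre grid
    (pixel (0, 0) centre sits at (pixel_size/2, pixel_size/2)).

    ``abs_threshold`` optionally floors the peak threshold in absolute
    intensity — on a stack, frames holding no bubble would otherwise have
    their noise peaks pass a purely frame-relative threshold.

    An all-zero or uniform frame yields an empty list, not an error.
    """
    frame = np.asarray(frame, dtype=float)
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must be in (0, 1)")
    if min_separation is None:
        min_separation = 2.0 * pixel_size
    if min_separation < pixel_size:
        raise ValueError("min_separation must be >= pixel_size")

    fmax = frame.max()
    if fmax <= 0 or np.ptp(frame) == 0:
        return []
    threshold = rel_threshold * fmax
    if abs_threshold is not None:
        threshold = max(threshold, abs_threshold)

    min_dist_px = max(int(round(min_separation / pixel_size)), 1)
    peaks = peak_local_max(
        frame,
        min_distance=min_dist_px,
        threshold_abs=threshold,
        exclude_border=False,
    )

    half = window_px // 2
    nz, nx = frame.shape
    detections: list[Detection] = []
    for iz, ix in peaks:
        i0, i1 = max(iz - half, 0), min(iz + half + 1, nz)
        j0, j1 = max(ix - half, 0), min(ix + half + 1, nx)
        win = frame[i0:i1, j0:j1]
        w = np.clip(win, 0.0, None)
        total = w.sum()
        if total <= 0:
            continue
        zi, xi = np.mgrid[i0:i1, j0:j1]
        cz = float((w * zi).sum() / total)
        cx = float((w * xi).sum() / total)
        detections.append(
            Detection(
                frame_index=frame_index,
                x_mm=(cx + 0.5) * pixel_size,
                z_mm=(cz + 0.5) * pixel_size,
                amplitude=float(frame[iz, ix]),
            )
        )
    # deterministic order: by z then x
    detections.sort(key=lambda d: (d.z_mm, d.x_mm))
    return detections


def detect_stack(
    stack: FrameStack,
    rel_threshold: float = 0.3,
    min_separation: float | None = None,
    window_px: int = 5,
) -> list[list[Detection]]:
    """Run :func:`detect_microbubbles` on every frame of a contrast stack.

    The relative threshold is anchored to a stack-level brightness scale —
    the median of the per-frame maxima, which tracks the typical
    single-bubble peak and is insensitive both to frames holding no
    bubble and to the occasional coincidental overlap of two bubbles in
    one pixel (which would inflate a global maximum and reject dimmer
    bubbles).  The threshold is additionally floored at six robust
    standard deviations (median + 6 x 1.4826 MAD) of the stack
    intensities, so a bubble-free acquisition yields no detections at all.
    """
    if stack.n_frames:
        vals = stack.frames.ravel()
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        noise_floor = med + 6.0 * 1.4826 * mad
        typical_peak = float(np.median(stack.frames.max(axis=(1, 2))))
        abs_threshold = max(rel_threshold * typical_peak, noise_floor)
    else:
        abs_threshold = None
    return [
        detect_microbubbles(
            stack.frames[k],
            stack.pixel_size,
            frame_index=k,
            rel_threshold=rel_threshold,
            min_separation=min_separation,
            window_px=window_px,
            abs_threshold=abs_threshold,
        )
        for k in range(stack.n_frames)
    ]
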