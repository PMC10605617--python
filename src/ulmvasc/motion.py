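"""Speckle-tracking motion estimation and position correction.

Tissue motion (dominated by ventilation in an abdominal acquisition) is
estimated on the B-mode stack by block matching against a reference frame:
a grid of blocks from the reference is located in each frame by normalized
cross-correlation, the integer peak is refined to sub-pixel precision by
parabolic interpolation, and block displacements are averaged into one
rigid translation per frame.  Microbubble positions are then shifted by
minus their frame's displacement before tracking.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import match_template

from .datatypes import Detection, FrameStack, MotionField

__all__ = ["estimate_motion", "correct_positions"]


def _parabolic_refine(corr: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Sub-pixel peak via separable 3-point parabola fits around ``peak``."""
    pi, pj = peak
    out = [float(pi), float(pj)]
    for axis, p in ((0, pi), (1, pj)):
        if 0 < p < corr.shape[axis] - 1:
            if axis == 0:
                c0, c1, c2 = corr[p - 1, pj], corr[p, pj], corr[p + 1, pj]
            else:
                c0, c1, c2 = corr[pi, p - 1], corr[pi, p], corr[pi, p + 1]
            denom = c0 - 2.0 * c1 + c2
            if abs(denom) > 1e-12:
                delta = 0.5 * (c0 - c2) / denom
                out[axis] = p + float(np.clip(delta, -0.5, 0.5))
    return out[0], out[1]


def estimate_motion(
    bmode: FrameStack,
    reference_index: int = 0,
    block_size: float = 3.2,
    search_radius: float = 0.8,
    grid: tuple[int, int] = (3, 3),
) -> MotionField:
    """Estimate per-frame rigid displacement relative to a reference frame.

    Parameters
    ----------
    bmode : FrameStack
        Tissue (B-mode) stack; speckle texture must be present.
    reference_index : int
        Frame every other frame is registered to (displacement 0 there).
    block_size, search_radius : float
        Block edge and maximum search excursion, both mm.  Motion larger
        than ``search_radius`` saturates: the estimate is clipped to the
        search window (documented failure mode, flagged by low confidence).
    grid : (int, int)
        Number of blocks (rows, cols) spread over the central region;
        block displacements are averaged, weighted by peak correlation.

    Returns
    -------
    MotionField
        Displacements ``(dx, dz)`` in mm that map the reference geometry
        onto each frame, plus the mean peak normalized cross-correlation
        per frame as a confidence score (below 0.5 means unreliable).
    """
    if bmode.n_frames == 0:
        raise ValueError("empty B-mode stack")
    px = bmode.pixel_size
    nz, nx = bmode.shape
    b = int(round(block_size / px))
    s = max(int(np.ceil(search_radius / px)), 1)
    if b + 2 * s >= min(nz, nx):
        raise ValueError("block plus search window does not fit in the frame")

    ref = bmode.frames[reference_index]
    # block top-left corners on a central grid
    gz, gx = grid
    margin_z = (nz - b - 2 * s) // 2
    margin_x = (nx - b - 2 * s) // 2
    iz = np.linspace(s + margin_z // 2, nz - b - s - margin_z // 2, gz).astype(int)
    ix = np.linspace(s + margin_x // 2, nx - b - s - margin_x // 2, gx).astype(int)

    disp = np.zeros((bmode.n_frames, 2))
    conf = np.zeros(bmode.n_frames)
    for k in range(bmode.n_frames):
        if k == reference_index:
            conf[k] = 1.0
            continue
        frame = bmode.frames[k]
        shifts = []
        weights = []
        for z0 in iz:
            for x0 in ix:
                block = ref[z0 : z0 + b, x0 : x0 + b]
                region = frame[z0 - s : z0 + b + s, x0 - s : x0 + b + s]
                corr = match_template(region, block)  # (2s+1, 2s+1)
                peak = np.unravel_index(np.argmax(corr), corr.shape)
                pz, pxx = _parabolic_refine(corr, peak)
                # offset s corresponds to zero displacement
                shifts.append(((pxx - s) * px, (pz - s) * px))
                weights.append(max(float(corr[peak]), 0.0))
        w = np.asarray(weights)
        sh = np.asarray(shifts)
        if w.sum() > 0:
            disp[k] = (sh * w[:, None]).sum(axis=0) / w.sum()
        conf[k] = float(w.mean())
    disp[reference_index] = 0.0
    return MotionField(displacements_mm=disp, reference_index=reference_index, confidence=conf)


def correct_positions(
    detections: list[list[Detection]], motion: MotionField
) -> list[list[Detection]]:
    """Shift every detection by minus its frame's estimated displacement.

    Frame order and within-frame order are preserved.  A detection frame
    index outside the motion field is an error: with interleaved B-mode the
    caller must have mapped every contrast frame to its nearest-in-time
    motion estimate first.
    """
    out: list[list[Detection]] = []
    for per_frame in detections:
        corrected = []
        for d in per_frame:
            if not 0 <= d.frame_index < motion.n_frames:
                raise ValueError(f"no motion estimate for frame {d.frame_index}")
            dx, dz = motion.displacements_mm[d.frame_index]
            corrected.append(
                Detection(
                    frame_index=d.frame_index,
                    x_mm=d.x_mm - dx,
                    z_mm=d.z_mm - dz,
                    amplitude=d.amplitude,
                )
            )
        out.append(corrected)
    return out
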