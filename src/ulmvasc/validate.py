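"""Recovery metrics against simulation ground truth.

A measured track *recovers* a true bubble trajectory when at least
``min_overlap`` of its points coincide, frame by frame, with that
trajectory within a spatial tolerance (one acquisition pixel by default).
Precision is the fraction of measured tracks recovering some true track;
recall is the fraction of true tracks (long enough to be trackable)
recovered by some measured track.
"""

from __future__ import annotations

import numpy as np

from .datatypes import GroundTruth, Track

__all__ = ["match_fraction", "track_recovery"]


def match_fraction(
    frames_a: np.ndarray,
    points_a: np.ndarray,
    frames_b: np.ndarray,
    points_b: np.ndarray,
    tol_mm: float,
) -> float:
    """Fraction of A's points that land within ``tol_mm`` of B's point in
    the same frame."""
    frames_b = np.asarray(frames_b)
    points_b = np.asarray(points_b)
    ok = 0
    for f, p in zip(frames_a, points_a):
        idx = np.flatnonzero(frames_b == f)
        if idx.size and np.linalg.norm(points_b[idx[0]] - p) <= tol_mm:
            ok += 1
    return ok / max(len(frames_a), 1)


def track_recovery(
    tracks: list[Track],
    truth: GroundTruth,
    tol_mm: float,
    min_true_length: int = 3,
    min_overlap: float = 0.8,
) -> tuple[float, float]:
    """(recall, precision) of measured tracks against the ground truth."""
    true_list = [
        (f, p) for f, p in truth.true_tracks.values() if len(f) >= min_true_length
    ]
    if not tracks:
        return (0.0 if true_list else 1.0), 1.0
    precision = float(
        np.mean(
            [
                max(
                    (
                        match_fraction(t.frame_indices, t.positions_mm, tf, tp, tol_mm)
                        for tf, tp in true_list
                    ),
                    default=0.0,
                )
                >= min_overlap
                for t in tracks
            ]
        )
    )
    if not true_list:
        return 1.0, precision
    recall = float(
        np.mean(
            [
                max(
                    match_fraction(tf, tp, t.frame_indices, t.positions_mm, tol_mm)
                    for t in tracks
                )
                >= min_overlap
                for tf, tp in true_list
            ]
        )
    )
    return recall, precision
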