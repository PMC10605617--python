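"""Hierarchical Kalman linking of microbubble detections into tracks.

Each open track carries a constant-velocity Kalman filter (state
``[x, z, vx, vz]``).  Frame by frame, predicted positions are matched to
the frame's detections by a globally optimal one-to-one assignment
(Hungarian) under a distance gate; unmatched detections open new candidate
tracks and unmatched tracks close immediately (no gap tolerance — a track
is a run of strictly consecutive frames).  "Hierarchical" means multi-pass
linking: pass 1 runs with the nominal gate over all detections, later
passes re-link the detections left over by earlier passes with the gate
widened by ``pass_gate_scale`` per pass.  Only tracks spanning at least
``min_track_length`` consecutive frames (default 3) are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datatypes import Detection, Track, TrackerParams

__all__ = ["track_microbubbles", "KalmanCV", "assign_detections"]


class KalmanCV:
    """Constant-velocity Kalman filter in the imaging plane.

    State ``[x, z, vx, vz]`` (mm, mm/s); only position is measured.
    Velocity is initialized to zero with inflated covariance at track
    birth, so the first update barely moves the position estimate while
    later updates let the velocity lock onto the bubble's flow.
    """

    def __init__(
        self,
        x0: np.ndarray,
        dt: float,
        process_noise: float,
        measurement_noise: float,
        init_speed_std: float = 20.0,
    ):
        self.x = np.array([x0[0], x0[1], 0.0, 0.0], dtype=float)
        self.P = np.diag([measurement_noise, measurement_noise, init_speed_std**2, init_speed_std**2])
        self.F = np.array(
            [[1, 0, dt, 0], [0, 1, 0, dt], [0, 0, 1, 0], [0, 0, 0, 1]], dtype=float
        )
        # white-acceleration process noise, discretized
        q = process_noise
        dt2, dt3, dt4 = dt**2, dt**3, dt**4
        self.Q = q * np.array(
            [
                [dt4 / 4, 0, dt3 / 2, 0],
                [0, dt4 / 4, 0, dt3 / 2],
                [dt3 / 2, 0, dt2, 0],
                [0, dt3 / 2, 0, dt2],
            ]
        )
        self.H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)
        self.R = measurement_noise * np.eye(2)

    def predict(self) -> np.ndarray:
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q
        return self.x[:2].copy()

    def update(self, z: np.ndarray) -> None:
        y = z - self.H @ self.x
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        self.P = (np.eye(4) - K @ self.H) @ self.P


def assign_detections(
    predicted: np.ndarray, detections: np.ndarray, gate: float
) -> list[tuple[int, int]]:
    """Globally optimal gated one-to-one assignment.

    Returns ``(track_idx, detection_idx)`` pairs whose Euclidean distance
    is within ``gate``, minimizing the total distance over all one-to-one
    matchings.  Pairs beyond the gate are infeasible.
    """
    if len(predicted) == 0 or len(detections) == 0:
        return []
    cost = np.linalg.norm(predicted[:, None, :] - detections[None, :, :], axis=2)
    feasible = cost <= gate
    if not feasible.any():
        return []
    big = gate * 1e6
    padded = np.where(feasible, cost, big)
    rows, cols = linear_sum_assignment(padded)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if feasible[r, c]]


@dataclass
class _OpenTrack:
    kf: KalmanCV
    frames: list[int] = field(default_factory=list)
    points: list[np.ndarray] = field(default_factory=list)
    det_keys: list[tuple[int, int]] = field(default_factory=list)


def _link_pass(
    per_frame: dict[int, list[tuple[int, Detection]]],
    frame_indices: list[int],
    gate: float,
    params: TrackerParams,
    dt: float,
) -> list[_OpenTrack]:
    """One linking pass over the given detections; returns finished tracks
    of any length (the caller applies the length filter)."""
    open_tracks: list[_OpenTrack] = []
    finished: list[_OpenTrack] = []

    prev_frame: int | None = None
    for f in frame_indices:
        dets = per_frame.get(f, [])
        # a skipped frame index closes everything (consecutive-frames rule)
        if prev_frame is not None and f != prev_frame + 1:
            finished.extend(open_tracks)
            open_tracks = []
        prev_frame = f

        positions = np.array([[d.x_mm, d.z_mm] for _, d in dets]) if dets else np.empty((0, 2))
        predicted = (
            np.array([t.kf.predict() for t in open_tracks])
            if open_tracks
            else np.empty((0, 2))
        )
        pairs = assign_detections(predicted, positions, gate)
        matched_tracks = {r for r, _ in pairs}
        matched_dets = {c for _, c in pairs}

        for r, c in pairs:
            t = open_tracks[r]
            t.kf.update(positions[c])
            t.frames.append(f)
            t.points.append(positions[c])
            t.det_keys.append((f, dets[c][0]))

        next_open = [t for i, t in enumerate(open_tracks) if i in matched_tracks]
        finished.extend(t for i, t in enumerate(open_tracks) if i not in matched_tracks)

        for c, (orig_idx, d) in enumerate(dets):
            if c in matched_dets:
                continue
            t = _OpenTrack(
                kf=KalmanCV(
                    np.array([d.x_mm, d.z_mm]),
                    dt,
                    params.process_noise,
                    params.measurement_noise,
                )
            )
            t.frames.append(f)
            t.points.append(np.array([d.x_mm, d.z_mm]))
            t.det_keys.append((f, orig_idx))
            next_open.append(t)
        open_tracks = next_open

    finished.extend(open_tracks)
    return finished


def track_microbubbles(
    detections: list[list[Detection]],
    params: TrackerParams | None = None,
    frame_rate: float = 55.0,
) -> list[Track]:
    """Link per-frame detections into microbubble tracks.

    ``detections[k]`` holds frame ``k``'s (motion-corrected) detections.
    Only tracks observed in at least ``params.min_track_length``
    consecutive frames are returned; no detection appears in more than one
    track.  Output order is deterministic: by first frame, then x, then z
    of the first point.
    """
    if params is None:
        params = TrackerParams()
    dt = 1.0 / frame_rate
    base_gate = params.gate_mm(frame_rate)

    # detections keyed (frame, within-frame index) so passes can exclude
    # the ones already consumed by emitted tracks
    remaining: dict[int, list[tuple[int, Detection]]] = {
        f: list(enumerate(per)) for f, per in enumerate(detections) if per
    }
    all_frames = sorted(remaining)
    emitted: list[_OpenTrack] = []

    for p in range(params.n_hierarchy_passes):
        if not remaining:
            break
        gate = base_gate * params.pass_gate_scale**p
        finished = _link_pass(remaining, all_frames, gate, params, dt)
        keep = [t for t in finished if len(t.frames) >= params.min_track_length]
        emitted.extend(keep)
        used = {key for t in keep for key in t.det_keys}
        new_remaining: dict[int, list[tuple[int, Detection]]] = {}
        for f, lst in remaining.items():
            left = [(i, d) for i, d in lst if (f, i) not in used]
            if left:
                new_remaining[f] = left
        remaining = new_remaining

    emitted.sort(key=lambda t: (t.frames[0], t.points[0][0], t.points[0][1]))
    return [
        Track(track_id=i, frame_indices=np.array(t.frames), positions_mm=np.array(t.points))
        for i, t in enumerate(emitted)
    ]
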