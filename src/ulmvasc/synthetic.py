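"""Synthetic vascular scenes with known ground truth.

Generates (i) branching quasi-planar vessel trees whose count controls
rarefaction and whose sinusoidal centreline perturbation controls
tortuosity, (ii) contrast-mode microbubble movies with interleaved
B-mode-like speckle for motion estimation, and (iii) micro-CT-like 3D tube
volumes with an exact per-voxel radius field.  Everything is a pure
function of its arguments including the seed.

The scenes emulate a rodent-kidney acquisition: cortical-radial-like
trunks running axially through three anatomical bands (cortex, outer
medulla, inner medulla), microbubbles advected along centrelines as plug
flow, an isotropic Gaussian point-spread function, and a slow global
sinusoidal translation standing in for ventilation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import (
    AcquisitionParams,
    FrameStack,
    GroundTruth,
    RadiusMap,
    ROIMask,
    VesselSegment,
    VesselTree,
    Volume3D,
)

__all__ = [
    "generate_vessel_tree",
    "subsample_tree",
    "simulate_mb_movie",
    "render_uct_volume",
    "region_band_mask",
    "rasterize_tree_mask",
    "true_region_density",
    "DEFAULT_EXTENT_MM",
    "REGION_BANDS",
]

#: Default square field of view, mm (x and z).
DEFAULT_EXTENT_MM = 12.8

#: Fractional z-extents of the anatomical bands: cortex nearest the probe,
#: then outer and inner medulla.
REGION_BANDS = {"CO": (0.0, 0.35), "OM": (0.35, 0.70), "IM": (0.70, 1.0)}

_SEG_SAMPLES = 200  # polyline samples per segment; keeps arc length within
# ~0.01% of the analytic sinusoid length


def _band_of(z_frac: float) -> str:
    for name, (lo, hi) in REGION_BANDS.items():
        if lo <= z_frac < hi:
            return name
    return "IM"


def _sinusoidal_polyline(
    p0: np.ndarray, p1: np.ndarray, amp: float, n_periods: float, perp: np.ndarray
) -> np.ndarray:
    """Chord ``p0 -> p1`` plus a sinusoidal deviation vanishing at both ends."""
    t = np.linspace(0.0, 1.0, _SEG_SAMPLES)
    base = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    if amp > 0:
        base = base + (amp * np.sin(2.0 * np.pi * n_periods * t))[:, None] * perp[None, :]
    return base


def generate_vessel_tree(
    n_root_vessels: int = 8,
    branching_depth: int = 2,
    tortuosity_amp: float = 0.0,
    dims: int = 2,
    seed: int = 0,
    extent_mm: float = DEFAULT_EXTENT_MM,
    tortuosity_periods: float = 1.0,
    root_radius_um: float = 100.0,
    root_speed_mm_s: float = 10.0,
    slab_thickness_mm: float = 1.0,
    edge_margin_mm: float = 0.4,
) -> VesselTree:
    """Generate a branching vascular tree with known tortuosity.

    Roots enter at the cortical face (z = 0) spread across x and run
    axially through the field of view, splitting into two children at each
    branching level.  ``tortuosity_amp`` (mm) is the amplitude of a
    sinusoidal deviation (``tortuosity_periods`` full periods per segment)
    superimposed perpendicular to each segment chord; 0 gives exactly
    straight polylines.  In 3D the tree is quasi-planar: confined to a slab
    of ``slab_thickness_mm`` in y.

    Radii shrink by 0.7 and flow speeds by 0.8 per branching level,
    coarsely mimicking a vascular cascade; both are surrogates, not
    haemodynamics.  Vessels stay ``edge_margin_mm`` away from the lateral
    field-of-view borders, as an operator frames the organ inside the FOV
    (a bubble hugging the border renders a clipped, biased blob).
    """
    if n_root_vessels < 1:
        raise ValueError("n_root_vessels must be >= 1")
    if branching_depth < 0:
        raise ValueError("branching_depth must be >= 0")
    if tortuosity_amp < 0:
        raise ValueError("tortuosity_amp must be >= 0")
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")

    rng = np.random.default_rng(seed)
    H = extent_mm
    n_levels = branching_depth + 1
    dz = H / n_levels  # axial span of each level's segments

    segments: list[VesselSegment] = []

    # root entry points, evenly spaced in x with jitter
    xs = (np.arange(n_root_vessels) + 0.5) / n_root_vessels * extent_mm
    xs = xs + rng.uniform(-0.25, 0.25, size=n_root_vessels) * extent_mm / n_root_vessels

    def grow(p0: np.ndarray, level: int) -> None:
        if level >= n_levels:
            return
        n_children = 1 if level == 0 else 2
        for child in range(n_children):
            lateral = rng.uniform(-0.35, 0.35) * dz
            if n_children == 2:
                lateral += (0.5 if child == 0 else -0.5) * dz * 0.8
            p1 = p0.copy()
            p1[0] = np.clip(p0[0] + lateral, edge_margin_mm, extent_mm - edge_margin_mm)
            if dims == 3:
                p1[1] = np.clip(
                    p0[1] + rng.uniform(-0.2, 0.2) * slab_thickness_mm,
                    0.0,
                    slab_thickness_mm,
                )
            p1[-1] = min(p0[-1] + dz, H)

            chord = p1 - p0
            L = np.linalg.norm(chord)
            if L == 0:
                continue
            u = chord / L
            if dims == 2:
                perp = np.array([-u[1], u[0]])
            else:
                # in-slab-plane perpendicular keeps the tree quasi-planar
                perp = np.array([-u[2], 0.0, u[0]])
                nrm = np.linalg.norm(perp)
                perp = perp / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])

            pts = _sinusoidal_polyline(p0, p1, tortuosity_amp, tortuosity_periods, perp)
            # keep the perturbed centreline inside the stated bounding box
            if dims == 2:
                pts = np.clip(pts, 0.0, [extent_mm, extent_mm])
            else:
                pts = np.clip(pts, 0.0, [extent_mm, slab_thickness_mm, extent_mm])
            z_mid = 0.5 * (p0[-1] + p1[-1])
            segments.append(
                VesselSegment(
                    points_mm=pts,
                    radius_um=root_radius_um * 0.7**level,
                    flow_speed_mm_s=root_speed_mm_s * 0.8**level,
                    region=_band_of(z_mid / H),
                )
            )
            grow(p1, level + 1)

    for x0 in xs:
        x0 = float(np.clip(x0, edge_margin_mm, extent_mm - edge_margin_mm))
        if dims == 2:
            p0 = np.array([x0, 0.0])
        else:
            p0 = np.array([x0, rng.uniform(0.3, 0.7) * slab_thickness_mm, 0.0])
        grow(p0, 0)

    if dims == 2:
        bbox = np.array([[0.0, extent_mm], [0.0, extent_mm]])
    else:
        bbox = np.array([[0.0, extent_mm], [0.0, slab_thickness_mm], [0.0, extent_mm]])
    return VesselTree(segments=segments, bounding_box_mm=bbox)


def subsample_tree(tree: VesselTree, keep_fraction: float, seed: int = 0) -> VesselTree:
    """Keep a random subset of segments — a rarefied version of the scene.

    The result is a set of independent vessels (connectivity is not
    preserved); it models microvessel loss, not pruned branches.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_keep = max(1, int(round(keep_fraction * len(tree.segments))))
    idx = rng.choice(len(tree.segments), size=n_keep, replace=False)
    kept = [tree.segments[i] for i in sorted(idx)]
    return VesselTree(segments=kept, bounding_box_mm=tree.bounding_box_mm.copy())


# ---------------------------------------------------------------------------
# Region masks and ground-truth density
# ---------------------------------------------------------------------------


def region_band_mask(
    extent_mm: float, pixel_size: float, origin_mm: tuple[float, float] = (0.0, 0.0)
) -> ROIMask:
    """Label image of the CO/OM/IM bands on a square grid."""
    n = int(round(extent_mm / pixel_size))
    labels = np.zeros((n, n), dtype=int)
    z = (np.arange(n) + 0.5) * pixel_size / extent_mm
    from .datatypes import REGION_LABELS

    for name, (lo, hi) in REGION_BANDS.items():
        rows = (z >= lo) & (z < hi if hi < 1.0 else z <= 1.0)
        labels[rows, :] = REGION_LABELS[name]
    return ROIMask(labels=labels, pixel_size=pixel_size, origin_mm=origin_mm)


def rasterize_tree_mask(
    tree: VesselTree, pixel_size: float, extent_mm: float | None = None
) -> np.ndarray:
    """Binary image of the tree's vessel lumina (disks along centrelines).

    2D trees only; used for ground-truth density, not for rendering.
    """
    if tree.ndim != 2:
        raise ValueError("rasterize_tree_mask expects a 2D tree")
    if extent_mm is None:
        extent_mm = float(tree.bounding_box_mm[-1, 1])
    n = int(round(extent_mm / pixel_size))
    mask = np.zeros((n, n), dtype=bool)
    for seg in tree.segments:
        r_px = max(seg.radius_um / 1000.0 / pixel_size, 0.5)
        # dense samples so consecutive stamps overlap
        d = np.linalg.norm(np.diff(seg.points_mm, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(d)])
        n_samp = max(int(arc[-1] / (pixel_size * 0.5)) + 1, 2)
        s = np.linspace(0, arc[-1], n_samp)
        # pixel (i, j) centre sits at ((j + 0.5) px, (i + 0.5) px)
        xs = np.interp(s, arc, seg.points_mm[:, 0]) / pixel_size - 0.5
        zs = np.interp(s, arc, seg.points_mm[:, 1]) / pixel_size - 0.5
        rr = int(np.ceil(r_px))
        for cx, cz in zip(xs, zs):
            i0, i1 = int(np.floor(cz - rr)), int(np.ceil(cz + rr)) + 1
            j0, j1 = int(np.floor(cx - rr)), int(np.ceil(cx + rr)) + 1
            i0, j0 = max(i0, 0), max(j0, 0)
            i1, j1 = min(i1, n), min(j1, n)
            if i0 >= i1 or j0 >= j1:
                continue
            ii, jj = np.mgrid[i0:i1, j0:j1]
            mask[i0:i1, j0:j1] |= (ii - cz) ** 2 + (jj - cx) ** 2 <= r_px**2
    return mask


def true_region_density(
    tree: VesselTree, pixel_size: float = 0.025, extent_mm: float | None = None
) -> dict[str, float]:
    """Ground-truth vessel-area fraction per anatomical band (rasterized)."""
    if extent_mm is None:
        extent_mm = float(tree.bounding_box_mm[-1, 1])
    mask = rasterize_tree_mask(tree, pixel_size, extent_mm)
    roi = region_band_mask(extent_mm, pixel_size)
    from .datatypes import REGION_LABELS

    out = {}
    for name in ("CO", "OM", "IM"):
        region = roi.labels == REGION_LABELS[name]
        out[name] = float(mask[region].sum() / region.sum()) if region.any() else 0.0
    return out


def analytic_region_density(tree: VesselTree, extent_mm: float | None = None) -> dict[str, float]:
    """Closed-form approximation: arc length x lumen width per band over
    the band area.  Each polyline piece contributes to the band its
    midpoint lies in; vessel overlap is ignored (adequate for sparse
    trees)."""
    if extent_mm is None:
        extent_mm = float(tree.bounding_box_mm[-1, 1])
    out = {name: 0.0 for name in REGION_BANDS}
    for seg in tree.segments:
        width = 2.0 * seg.radius_um / 1000.0
        pieces = np.linalg.norm(np.diff(seg.points_mm, axis=0), axis=1)
        z0s = seg.points_mm[:-1, -1]
        z1s = seg.points_mm[1:, -1]
        for L, z0, z1 in zip(pieces, z0s, z1s):
            zlo, zhi = sorted((z0, z1))
            if zhi - zlo < 1e-12:  # piece parallel to the band boundaries
                out[_band_of(0.5 * (zlo + zhi) / extent_mm)] += L * width
                continue
            for name, (flo, fhi) in REGION_BANDS.items():
                ov = max(
                    0.0, min(zhi, fhi * extent_mm) - max(zlo, flo * extent_mm)
                )
                out[name] += L * width * ov / (zhi - zlo)
    for name, (lo, hi) in REGION_BANDS.items():
        area = extent_mm * extent_mm * (hi - lo)
        out[name] /= area
    return out


# ---------------------------------------------------------------------------
# Microbubble movie
# ---------------------------------------------------------------------------


def _arc_param(seg: VesselSegment) -> tuple[np.ndarray, np.ndarray]:
    d = np.linalg.norm(np.diff(seg.points_mm, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(d)])
    return arc, seg.points_mm


def _pos_at(arc: np.ndarray, pts: np.ndarray, s: float) -> np.ndarray:
    return np.array([np.interp(s, arc, pts[:, k]) for k in range(pts.shape[1])])


def simulate_mb_movie(
    tree: VesselTree, acq: AcquisitionParams
) -> tuple[FrameStack, FrameStack, GroundTruth]:
    """Simulate a contrast movie plus a B-mode-like stack for motion work.

    Bubbles arrive as a Poisson process of total rate ``acq.mb_influx_rate``
    (assigned to segments uniformly at random), enter at the upstream end,
    advect along the centreline at the segment flow speed (plug flow), and
    leave at the far end.  Each frame renders every active bubble as an
    isotropic Gaussian of ``psf_sigma`` plus i.i.d. Gaussian noise.  A
    global sinusoidal translation (``motion_amplitude``/``motion_period``)
    displaces both stacks; the ground truth stores motion-free geometry, so
    positions measured on the frames carry the motion and must be corrected
    before comparison.

    Returns ``(contrast, bmode, ground_truth)``.
    """
    if not tree.segments:
        raise ValueError("cannot simulate a movie from an empty tree")
    if tree.ndim != 2:
        raise ValueError("simulate_mb_movie expects a 2D tree")

    rng = np.random.default_rng(acq.seed)
    extent = float(tree.bounding_box_mm[-1, 1])
    n_px = int(round(extent / acq.pixel_size))
    T = acq.n_frames / acq.frame_rate

    # --- bubble schedule -------------------------------------------------
    n_bubbles = rng.poisson(acq.mb_influx_rate * T)
    birth_times = np.sort(rng.uniform(0.0, T, size=n_bubbles))
    seg_ids = rng.integers(0, len(tree.segments), size=n_bubbles)
    amplitudes = rng.uniform(0.6, 1.0, size=n_bubbles)

    arcs = [_arc_param(s) for s in tree.segments]

    # --- ventilation-like motion ----------------------------------------
    t_frames = np.arange(acq.n_frames) / acq.frame_rate
    theta = np.deg2rad(acq.motion_direction_deg)
    direction = np.array([np.cos(theta), np.sin(theta)])
    if acq.motion_period > 0:
        phase = np.sin(2.0 * np.pi * t_frames / acq.motion_period)
    else:
        phase = np.zeros_like(t_frames)
    motion = acq.motion_amplitude * phase[:, None] * direction[None, :]  # (n, 2)

    # --- per-frame bubble positions (motion-free) ------------------------
    true_detections: list[list[tuple[float, float, int]]] = [[] for _ in range(acq.n_frames)]
    track_frames: dict[int, list[int]] = {}
    track_pos: dict[int, list[np.ndarray]] = {}

    jitter_per_frame = (
        rng.normal(0.0, acq.mb_jitter_sigma, size=(n_bubbles, acq.n_frames, 2))
        if acq.mb_jitter_sigma > 0
        else None
    )

    frames = np.zeros((acq.n_frames, n_px, n_px), dtype=float)
    zz, xx = np.mgrid[0:n_px, 0:n_px]
    sigma_px = acq.psf_sigma / acq.pixel_size

    for b in range(n_bubbles):
        arc, pts = arcs[seg_ids[b]]
        seg = tree.segments[seg_ids[b]]
        L = arc[-1]
        v = seg.flow_speed_mm_s
        if v == 0:
            continue
        dwell = L / abs(v)
        for k in range(acq.n_frames):
            dt = t_frames[k] - birth_times[b]
            if dt < 0 or dt > dwell:
                continue
            s = v * dt if v > 0 else L + v * dt
            p = _pos_at(arc, pts, s)
            if jitter_per_frame is not None:
                p = p + jitter_per_frame[b, k]
            if not (0 <= p[0] <= extent and 0 <= p[1] <= extent):
                continue
            true_detections[k].append((float(p[0]), float(p[1]), b))
            track_frames.setdefault(b, []).append(k)
            track_pos.setdefault(b, []).append(p)
            # render with motion applied
            pm = p + motion[k]
            cx = pm[0] / acq.pixel_size - 0.5
            cz = pm[1] / acq.pixel_size - 0.5
            w = int(np.ceil(4 * sigma_px))
            i0, i1 = max(int(cz) - w, 0), min(int(cz) + w + 1, n_px)
            j0, j1 = max(int(cx) - w, 0), min(int(cx) + w + 1, n_px)
            if i0 >= i1 or j0 >= j1:
                continue
            blob = amplitudes[b] * np.exp(
                -((zz[i0:i1, j0:j1] - cz) ** 2 + (xx[i0:i1, j0:j1] - cx) ** 2)
                / (2.0 * sigma_px**2)
            )
            frames[k, i0:i1, j0:j1] += blob

    if acq.noise_sigma > 0:
        frames += rng.normal(0.0, acq.noise_sigma, size=frames.shape)

    contrast = FrameStack(
        frames=frames, pixel_size=acq.pixel_size, frame_rate=acq.frame_rate, kind="contrast"
    )

    # --- B-mode-like speckle stack ---------------------------------------
    bmode = _render_bmode(n_px, acq, motion, rng)

    truth = GroundTruth(
        true_detections=true_detections,
        true_tracks={
            b: (np.asarray(track_frames[b]), np.asarray(track_pos[b]))
            for b in track_frames
        },
        true_motion_mm=motion,
        true_density_per_region=true_region_density(tree),
        true_tortuosity_per_segment=np.array([s.tortuosity for s in tree.segments]),
    )
    return contrast, bmode, truth


def _render_bmode(
    n_px: int, acq: AcquisitionParams, motion: np.ndarray, rng: np.random.Generator
) -> FrameStack:
    """Textured tissue frames: a static speckle field resampled under the
    per-frame translation, plus mild frame-to-frame decorrelation noise."""
    pad = int(np.ceil(np.abs(motion).max() / acq.pixel_size)) + 4
    texture = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, size=(n_px + 2 * pad, n_px + 2 * pad)), 1.0
    )
    texture = (texture - texture.min()) / (texture.max() - texture.min() + 1e-12)
    frames = np.empty((len(motion), n_px, n_px))
    base_i, base_j = np.mgrid[0:n_px, 0:n_px]
    for k, (dx, dz) in enumerate(motion):
        # frame_k(x) = texture(x - d_k): tissue displaced by +d_k
        ci = base_i + pad - dz / acq.pixel_size
        cj = base_j + pad - dx / acq.pixel_size
        frames[k] = ndimage.map_coordinates(texture, [ci, cj], order=3, mode="nearest")
    frames += rng.normal(0.0, 0.01, size=frames.shape)
    return FrameStack(
        frames=frames, pixel_size=acq.pixel_size, frame_rate=acq.frame_rate, kind="bmode"
    )


# ---------------------------------------------------------------------------
# Micro-CT-like volume
# ---------------------------------------------------------------------------


def render_uct_volume(
    tree: VesselTree,
    voxel_size_um: float = 26.5,
    noise_sigma: float = 0.0,
    seed: int = 0,
    vessel_intensity: float = 1.0,
    background_intensity: float = 0.0,
    pad_vox: int = 4,
) -> tuple[Volume3D, RadiusMap]:
    """Voxelize a 3D tree into a micro-CT-like intensity volume.

    Voxels within a segment's radius of its centreline take
    ``vessel_intensity``, the rest ``background_intensity``; i.i.d.
    Gaussian noise of ``noise_sigma`` is added on top.  Also returns the
    exact per-voxel radius field (voxel units; where tubes overlap the
    larger radius wins), the ground truth for local-thickness estimation.
    """
    if voxel_size_um <= 0:
        raise ValueError("voxel_size_um must be positive")
    if tree.ndim != 3:
        raise ValueError("render_uct_volume expects a 3D tree")
    if not tree.segments:
        raise ValueError("cannot render an empty tree")

    vox_mm = voxel_size_um / 1000.0
    lo = tree.bounding_box_mm[:, 0]
    hi = tree.bounding_box_mm[:, 1]
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / vox_mm)) + 2 * pad_vox for a in range(3))

    radius = np.zeros(shape, dtype=float)
    for seg in tree.segments:
        r_vox = seg.radius_um / voxel_size_um
        d = np.linalg.norm(np.diff(seg.points_mm, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(d)])
        n_samp = max(int(arc[-1] / (vox_mm * 0.4)) + 1, 2)
        s = np.linspace(0, arc[-1], n_samp)
        samples_vox = np.stack(
            [np.interp(s, arc, seg.points_mm[:, a]) for a in range(3)], axis=1
        )
        samples_vox = (samples_vox - lo[None, :]) / vox_mm + pad_vox
        rr = int(np.ceil(r_vox))
        for c in samples_vox:
            sl = []
            ok = True
            for a in range(3):
                a0 = max(int(np.floor(c[a] - rr)), 0)
                a1 = min(int(np.ceil(c[a] + rr)) + 1, shape[a])
                if a0 >= a1:
                    ok = False
                    break
                sl.append((a0, a1))
            if not ok:
                continue
            gi, gj, gk = np.mgrid[sl[0][0]:sl[0][1], sl[1][0]:sl[1][1], sl[2][0]:sl[2][1]]
            inside = (gi - c[0]) ** 2 + (gj - c[1]) ** 2 + (gk - c[2]) ** 2 <= r_vox**2
            sub = radius[sl[0][0]:sl[0][1], sl[1][0]:sl[1][1], sl[2][0]:sl[2][1]]
            np.maximum(sub, np.where(inside, r_vox, 0.0), out=sub)

    data = np.where(radius > 0, vessel_intensity, background_intensity)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    return Volume3D(data=data, voxel_size_um=voxel_size_um), RadiusMap(
        radius_vox=radius, voxel_size_um=voxel_size_um
    )


def synthetic_kidney_masks(
    shape: tuple[int, int, int], medulla_scale: float = 0.55
) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal kidney and concentric medulla masks for phantom studies.

    The kidney is an axis-aligned ellipsoid filling ~90% of the volume;
    the medulla is a concentric ellipsoid scaled by ``medulla_scale``.
    The cortex follows as the exact set difference.
    """
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    c = [(s - 1) / 2.0 for s in shape]
    a = [0.45 * s for s in shape]
    q = sum(((g - ci) / ai) ** 2 for g, ci, ai in zip((zz, yy, xx), c, a))
    kidney = q <= 1.0
    qm = sum(
        ((g - ci) / (ai * medulla_scale)) ** 2 for g, ci, ai in zip((zz, yy, xx), c, a)
    )
    medulla = qm <= 1.0
    return kidney, medulla & kidney


def sparsify_labels(labels: np.ndarray, stride: int = 5, axis: int = 0) -> np.ndarray:
    """Keep annotations only on every ``stride``-th slice along ``axis``,
    emulating a manual polygon segmentation of every fifth coronal slice."""
    labels = np.asarray(labels)
    out = np.zeros_like(labels)
    idx = [slice(None)] * labels.ndim
    n = labels.shape[axis]
    keep = list(range(0, n, stride))
    if keep[-1] != n - 1:
        keep.append(n - 1)
    for k in keep:
        idx[axis] = k
        out[tuple(idx)] = labels[tuple(idx)]
    return out
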