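# Methods

`ulmvasc` implements a desk-scale model of a renal super-resolution
ultrasound (SRUS / ultrasound localization microscopy) study: microbubble
trajectories are reconstructed from contrast-mode frame stacks and used as
vessel surrogates, from which two structural read-outs — patch-based
vascular density and distance-metric tortuosity — are computed inside
anatomical regions of interest. A parallel branch quantifies small-vessel
volume density in contrast-cast micro-CT volumes. Because no imaging data
ship with the package, a synthetic-scene generator produces every input
with known ground truth; all quantitative guarantees are demonstrated
against that ground truth.

## Synthetic scenes

**Vessel trees.** A scene is a set of polyline centrelines with
per-segment radius (µm), signed flow speed (mm/s) and an anatomical label.
Trees grow from `n_root_vessels` entry points on the cortical face,
splitting into two children per level for `branching_depth` levels; radii
shrink by 0.7 and speeds by 0.8 per level — a coarse vascular cascade, not
haemodynamics. The field of view (default 12.8 × 12.8 mm) is split into
three axial bands, cortex (CO, 0–35 %), outer medulla (OM, 35–70 %) and
inner medulla (IM, 70–100 %), mimicking the banded anatomy of a
longitudinal kidney section. Tortuosity is injected as a sinusoidal
deviation of amplitude `tortuosity_amp` (mm, one full period per segment)
perpendicular to each segment chord: amplitude 0 gives exactly straight
polylines (distance metric exactly 1), and the polyline arc length matches
the analytic sine arc length to ≲0.01 % at the 200-point sampling used.
Vessels keep a 0.4 mm margin from the lateral image borders: a bubble
hugging the border renders a clipped point-spread function whose centroid
is biased, which is an imaging artefact rather than a tracking property,
and operators frame the organ inside the FOV anyway.

**Rarefaction** is modelled by keeping a uniformly random subset of a
scene's segments (`subsample_tree`), i.e. microvessel drop-out, not pruned
subtrees; connectivity is deliberately not preserved.

**Microbubble movies.** Bubbles arrive as a Poisson process with total
rate `mb_influx_rate` (default 5 s⁻¹), are assigned to segments uniformly
at random, enter at the upstream end and advect along the centreline as
plug flow (no radial offset; optional Brownian jitter defaults to 0).
Each frame renders active bubbles as isotropic Gaussians
(`psf_sigma` = 0.15 mm) with per-bubble amplitude U(0.6, 1) on a 0.1 mm
pixel grid at 55 Hz, plus i.i.d. Gaussian noise (σ = 0.01, intensities in
[0, 1] — thresholds downstream are relative, so the intensity scale is
arbitrary). Tissue motion is a single global sinusoidal translation
(ventilation-like; default 0.1 mm amplitude, 2 s period, axial) applied to
both the contrast frames and a B-mode-like stack, which is a static
smoothed-speckle texture resampled under the per-frame shift with cubic
interpolation plus mild decorrelation noise. The ground-truth object
records motion-free bubble positions per frame, per-bubble trajectories,
the injected motion, per-segment tortuosity, and lumen-area density per
band (rasterized disks along the centrelines).

What the movies do **not** model: acoustic wave propagation, the
amplitude-modulation pulse sequence (contrast separation is assumed
perfect), depth-dependent PSF anisotropy, non-rigid or cardiac motion,
bubble disruption, and in-plane concentration gradients. Passing recovery
tests therefore shows the *processing chain* is correct under its stated
assumptions, not that it is robust to every in vivo confounder.

**Micro-CT volumes.** 3D trees are voxelized on an isotropic grid
(default 26.5 µm voxels): a voxel is vessel if it lies within a segment's
radius of its centreline (spherically capped tubes), and the exact tube
radius is emitted per foreground voxel as the ground truth for local-
thickness estimation. Phantom kidneys are concentric ellipsoids (kidney
and medulla), with the cortex the exact set difference.

## ULM processing chain

**Detection.** Per frame, local maxima above `rel_threshold` (default
0.3) times a brightness scale, with non-maximum suppression over
`min_separation` (default 2 px), refined to sub-pixel positions by an
intensity-weighted centroid over a 5 × 5 px window. On stacks the
brightness scale is the median of per-frame maxima — a global maximum
would be inflated by rare two-bubble pixel coincidences and reject dimmer
bubbles, while a purely frame-relative threshold would promote the noise
floor of bubble-free frames. A floor of median + 6 × 1.4826 MAD of the
stack intensities makes a bubble-free acquisition yield zero detections.

**Motion estimation.** Block matching on the B-mode stack against a
reference frame (default frame 0, configurable): a 3 × 3 grid of
3.2 mm blocks is located in each frame by normalized cross-correlation
within a ±0.8 mm search window, each peak refined by separable 3-point
parabolic interpolation (clamped to ±0.5 px), and block shifts averaged
weighted by peak correlation. Motion beyond the search radius saturates
(documented failure mode); mean peak correlation below 0.5 flags an
unreliable frame. Detections are corrected by subtracting their frame's
displacement before tracking.

**Tracking.** Each open track carries a constant-velocity Kalman filter
(state `[x, z, vx, vz]`; velocity born at zero with inflated covariance of
(20 mm/s)²; white-acceleration process noise, position-only measurements).
Per frame, predicted positions are matched to detections by a globally
optimal one-to-one assignment (Hungarian) under a distance gate, default
`max_speed / frame_rate` with `max_speed` 20 mm/s. Unmatched tracks close
immediately — zero gap tolerance, because a track is defined as a run of
strictly consecutive frames — and unmatched detections open candidates.
"Hierarchical" means multi-pass linking: pass 1 with the nominal gate;
each later pass (default one more) re-links the detections left unused by
emitted tracks with the gate widened ×2, catching faster bubbles without
loosening the gate for everything. Only tracks spanning ≥ 3 consecutive
frames are emitted. Determinism: output tracks are sorted by first frame,
then x, then z of the first point; the Hungarian solution is deterministic
given the cost matrix.

**Accumulation and read-outs.** Tracks are accumulated on a 25 µm
super-resolution grid (fine enough that sub-75 µm vessels are resolvable;
the grid spacing is configurable): consecutive points are joined by
rasterized line segments, a pixel is track-filled if any segment crosses
it, and a direction map stores the circular mean flow angle per pixel
(used only for the colour-wheel rendering, never for quantification).

*Density*: 2 × 2 mm² patches tile each region's bounding box with 50 %
overlap; a patch is evaluated only if ≥ 50 % of its pixels carry the
region label (border patches are otherwise diluted by background), and
scores track-filled region pixels over region pixels in the patch, 0 to 1;
the mean over patches × 100 is the region's density percentage. The patch
grid is anchored to the region bounding box and the denominator counts
super-resolution-grid pixels; both choices are configuration, not physics.

*Tortuosity*: per track, the distance metric — path length over
start-to-end chord — which is ≥ 1 with equality exactly for collinear
points. A track belongs to the region holding the majority of its points
(ties → region of the first point). Tracks whose chord is below one grid
pixel (loops) are excluded from the mean and tallied. A sum-of-angles
variant (total absolute turning angle per path length) is provided as a
clearly secondary metric; no headline quantity uses it.

## Micro-CT branch

The kidney mask grows 26-connected from a seed voxel over an explicit
intensity threshold and is closed with a 2-voxel ball (a deterministic
stand-in for manual smoothing at the hilum). The medulla is annotated on
sparse slices (every 5th by default) and filled by shape-based
interpolation: per label, the signed distance transform of each annotated
slice is interpolated linearly along the slice axis and thresholded at
zero; annotated slices are reproduced exactly, overlaps resolve to the
most interior label, and slices outside the annotated range stay
background. The cortex is the exact set difference kidney ∖ medulla.

Vessels are an explicit intensity threshold inside the kidney — required
input by design, mirroring per-scan manual tuning. The local radius of
each vessel voxel is its *local thickness*: the radius of the largest
sphere fully inside the segmentation containing the voxel, computed by
painting distance-transform spheres in descending radius order; on
cylinder phantoms this is bit-identical to a brute-force inscribed-sphere
oracle, and an isolated voxel gets radius 1 (its distance to the nearest
background neighbour). Thresholding the radius map at 10 voxels (cortex)
or 6 voxels (medulla; ≈ 265 µm and ≈ 159 µm at 26.5 µm voxels) splits the
segmentation into small and large vessels, a partition by construction.
Regional density is |small ∩ region| / |region ∖ large|: large-vessel
voxels leave numerator and denominator both, so the value is the
small-vessel fraction of the remaining tissue — the one reading of
"large vessels removed" that keeps the ratio interpretable, and the one
this package commits to.

## Problem sizes and numerical choices

Tests and the acceptance script run simulations sized for a single CPU:
110-frame movies (2 s) for tracking/motion recovery, 550 frames at
20 bubbles/s for the rarefaction comparison (enough influx that every
segment is traversed several times, so track coverage saturates per
vessel), 330 frames at 10 bubbles/s for the tortuosity sweep, and
cylinder phantoms of radius 3–12 voxels for the micro-CT chain. The
rarefaction comparison checks the *ratio* of measured densities between
paired scenes against the rasterized ground-truth ratio; absolute
track-raster density is line-based and not commensurate with lumen-area
density. Floats are written with 6 significant digits; CSV column orders
are fixed; every tabular output carries a 12-hex-digit hash of the
scientific configuration (output paths excluded).

## Known limitations

- Plug flow on shared centrelines means repeated traversals add no new
  raster coverage; measured density saturates per vessel and carries no
  flow-volume information.
- The tracker assumes at most one detection per bubble per frame and no
  gaps; real dropout (bubble disruption, out-of-plane motion) shortens
  tracks rather than bridging them, exactly as in the modelled protocol.
- Motion is rigid and global; the estimator averages block shifts and
  will not capture shear or rotation.
- Local thickness is resolution-limited: radii below ~2 voxels are
  quantized coarsely, and the sphere-painting cost grows with foreground
  volume × radius³, which is fine at phantom scale but would want a
  ridge-restricted variant for full organ scans.
- Region labels in the synthetic scenes are axis-aligned bands; real ROI
  geometry (arcuate-vessel delineation) must be supplied as label images.
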