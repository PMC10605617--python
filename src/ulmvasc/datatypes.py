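"""Core containers shared across the ULM / micro-CT pipeline.

Conventions: in-plane coordinates are ``(x, z)`` in millimetres (lateral,
axial), image arrays are indexed ``[row, col] == [z, x]``, radii are in
micrometres unless a function explicitly works in voxel units, and time is
expressed through integer frame indices at a fixed frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FrameStack",
    "Detection",
    "MotionField",
    "Track",
    "TrackerParams",
    "SRUSImage",
    "ROIMask",
    "PatchDensityResult",
    "TortuosityResult",
    "VesselSegment",
    "VesselTree",
    "AcquisitionParams",
    "GroundTruth",
    "Volume3D",
    "RegionMasks3D",
    "RadiusMap",
    "RegionDensityResult",
    "REGION_LABELS",
]

#: Integer codes used in ROI label images and segment region labels.
REGION_LABELS = {"background": 0, "CO": 1, "OM": 2, "IM": 3}


@dataclass
class FrameStack:
    """Time-ordered stack of 2D intensity frames with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, nz, nx)
        Intensity images, arbitrary units.
    pixel_size : float
        Isotropic in-plane pixel size in mm.
    frame_rate : float
        Frames per second (Hz).
    kind : {"contrast", "bmode"}
        Contrast-mode (microbubble) or B-mode (tissue) data.
    """

    frames: np.ndarray
    pixel_size: float
    frame_rate: float
    kind: str = "contrast"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, nz, nx) array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.kind not in ("contrast", "bmode"):
            raise ValueError(f"unknown stack kind {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width_x, height_z) of the field of view in mm."""
        nz, nx = self.shape
        return nx * self.pixel_size, nz * self.pixel_size


@dataclass(frozen=True)
class Detection:
    """One sub-pixel microbubble localization in one frame."""

    frame_index: int
    x_mm: float
    z_mm: float
    amplitude: float


@dataclass
class MotionField:
    """Per-frame rigid in-plane displacement relative to a reference frame.

    ``displacements_mm[k] = (dx, dz)`` is the shift that moves the reference
    frame onto frame ``k``; it is therefore *subtracted* from positions
    measured in frame ``k`` to bring them into the reference geometry.
    """

    displacements_mm: np.ndarray  # (n_frames, 2) -> (dx, dz)
    reference_index: int
    confidence: np.ndarray | None = None  # peak NCC per frame

    def __post_init__(self) -> None:
        self.displacements_mm = np.asarray(self.displacements_mm, dtype=float)
        if self.displacements_mm.ndim != 2 or self.displacements_mm.shape[1] != 2:
            raise ValueError("displacements_mm must have shape (n_frames, 2)")
        ref = self.displacements_mm[self.reference_index]
        if not np.allclose(ref, 0.0, atol=1e-12):
            raise ValueError("displacement at the reference frame must be (0, 0)")

    @property
    def n_frames(self) -> int:
        return self.displacements_mm.shape[0]


@dataclass
class Track:
    """One microbubble trajectory: consecutive frames, sub-pixel positions."""

    track_id: int
    frame_indices: np.ndarray  # (n,)
    positions_mm: np.ndarray  # (n, 2) -> (x, z)

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if len(self.frame_indices) != len(self.positions_mm):
            raise ValueError("frame_indices and positions_mm length mismatch")
        if len(self.frame_indices) >= 2 and np.any(np.diff(self.frame_indices) != 1):
            raise ValueError("track frame indices must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.frame_indices)

    @property
    def path_length_mm(self) -> float:
        """Sum of Euclidean inter-point distances along the track."""
        if len(self) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.positions_mm, axis=0), axis=1)))

    @property
    def chord_mm(self) -> float:
        """Straight start-to-end distance."""
        if len(self) < 2:
            return 0.0
        return float(np.linalg.norm(self.positions_mm[-1] - self.positions_mm[0]))


@dataclass
class TrackerParams:
    """Parameters of the hierarchical Kalman linker.

    ``max_link_distance`` (the gate) defaults to the maximum expected
    microbubble speed divided by the frame rate; pass an explicit value to
    override. Gates are in mm, noise terms are variances of the
    constant-velocity Kalman model.
    """

    max_link_distance: float | None = None
    max_speed_mm_s: float = 20.0
    process_noise: float = 1e-4
    measurement_noise: float = 1e-4
    min_track_length: int = 3
    n_hierarchy_passes: int = 2
    pass_gate_scale: float = 2.0

    def __post_init__(self) -> None:
        if self.max_link_distance is not None and self.max_link_distance <= 0:
            raise ValueError("max_link_distance must be positive")
        if self.min_track_length < 1:
            raise ValueError("min_track_length must be >= 1")
        if self.n_hierarchy_passes < 1:
            raise ValueError("n_hierarchy_passes must be >= 1")

    def gate_mm(self, frame_rate: float) -> float:
        if self.max_link_distance is not None:
            return self.max_link_distance
        return self.max_speed_mm_s / frame_rate


@dataclass
class SRUSImage:
    """Super-resolved raster of accumulated tracks plus flow directions.

    ``raster`` is binary (a pixel is 1 if any track segment crosses it);
    ``direction`` holds the circular mean flow angle in radians on
    track-filled pixels and NaN elsewhere.
    """

    raster: np.ndarray
    direction: np.ndarray
    pixel_size: float  # mm, super-resolution grid
    origin_mm: tuple[float, float]  # (x0, z0) of pixel (0, 0) centre

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.raster.shape != self.direction.shape:
            raise ValueError("raster and direction map must share a shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class ROIMask:
    """Region label image on the super-resolution grid.

    Labels follow :data:`REGION_LABELS`: 0 background, 1 cortex (CO),
    2 outer medulla (OM), 3 inner medulla (IM).
    """

    labels: np.ndarray
    pixel_size: float
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def region_code(self, region: str | int) -> int:
        if isinstance(region, str):
            try:
                return REGION_LABELS[region]
            except KeyError:
                raise ValueError(f"unknown region {region!r}") from None
        return int(region)


@dataclass
class PatchDensityResult:
    """Patch-based vascular density inside one ROI region."""

    region: str
    patch_centers_mm: np.ndarray  # (n_patches, 2)
    patch_densities: np.ndarray  # fractions in [0, 1]
    n_candidate_patches: int = 0

    @property
    def mean_density_percent(self) -> float:
        """Arithmetic mean of patch densities, as a percentage."""
        if len(self.patch_densities) == 0:
            return float("nan")
        return float(np.mean(self.patch_densities) * 100.0)


@dataclass
class TortuosityResult:
    """Per-track distance-metric tortuosity for one ROI region."""

    region: str
    track_ids: np.ndarray
    distance_metric: np.ndarray  # >= 1, path / chord
    n_excluded_zero_chord: int = 0
    sum_of_angles: np.ndarray | None = None  # optional secondary metric, rad/mm

    @property
    def mean_distance_metric(self) -> float:
        if len(self.distance_metric) == 0:
            return float("nan")
        return float(np.mean(self.distance_metric))


# ---------------------------------------------------------------------------
# Synthetic-scene types
# ---------------------------------------------------------------------------


@dataclass
class VesselSegment:
    """One vessel centreline: a polyline with radius, flow speed and region."""

    points_mm: np.ndarray  # (n, 2) or (n, 3)
    radius_um: float
    flow_speed_mm_s: float  # signed along the polyline orientation
    region: str = "background"  # one of REGION_LABELS or "background"

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=float)
        if self.points_mm.ndim != 2 or len(self.points_mm) < 2:
            raise ValueError("a segment polyline needs >= 2 points")
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")

    @property
    def arc_length_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1)))

    @property
    def chord_mm(self) -> float:
        return float(np.linalg.norm(self.points_mm[-1] - self.points_mm[0]))

    @property
    def tortuosity(self) -> float:
        """Distance metric of the centreline (>= 1, 1 iff straight)."""
        chord = self.chord_mm
        if chord == 0:
            return float("inf")
        return self.arc_length_mm / chord


@dataclass
class VesselTree:
    """A branching vascular tree with per-segment radii and flow speeds."""

    segments: list[VesselSegment]
    bounding_box_mm: np.ndarray  # (ndim, 2) -> (lo, hi) per axis

    def __post_init__(self) -> None:
        self.bounding_box_mm = np.asarray(self.bounding_box_mm, dtype=float)

    @property
    def ndim(self) -> int:
        return self.segments[0].points_mm.shape[1] if self.segments else 0

    def segments_in_region(self, region: str) -> list[VesselSegment]:
        return [s for s in self.segments if s.region == region]


@dataclass
class AcquisitionParams:
    """Synthetic contrast/B-mode acquisition settings.

    Defaults mirror the in vivo protocol this generator emulates: a 55 Hz
    amplitude-modulation sequence interleaved with B-mode (the 10 MHz centre
    frequency and 0.1 mechanical index are metadata only — no acoustics are
    simulated). ``mb_influx_rate`` is the total Poisson rate of new
    microbubbles entering the field of view; it stands in for a continuous
    contrast infusion, whose in-plane concentration the protocol does not
    pin down.
    """

    frame_rate: float = 55.0
    n_frames: int = 220
    pixel_size: float = 0.1  # mm
    psf_sigma: float = 0.15  # mm, isotropic Gaussian point-spread
    mb_influx_rate: float = 5.0  # bubbles / s over the whole tree
    noise_sigma: float = 0.01  # additive Gaussian, intensity in [0, 1]
    motion_amplitude: float = 0.1  # mm, ventilation-like global translation
    motion_period: float = 2.0  # s
    motion_direction_deg: float = 90.0  # axial (z) by default
    mb_jitter_sigma: float = 0.0  # mm, optional Brownian jitter (off)
    seed: int = 0
    center_frequency_mhz: float = 10.0  # metadata only
    mechanical_index: float = 0.1  # metadata only

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class GroundTruth:
    """Everything the simulator knows; enables parameter-recovery tests."""

    # per frame: list of (x_mm, z_mm, bubble_id), motion-free geometry
    true_detections: list[list[tuple[float, float, int]]]
    # bubble_id -> (frame_indices, positions (n, 2)), motion-free geometry
    true_tracks: dict[int, tuple[np.ndarray, np.ndarray]]
    true_motion_mm: np.ndarray  # (n_frames, 2)
    true_density_per_region: dict[str, float]
    true_tortuosity_per_segment: np.ndarray


# ---------------------------------------------------------------------------
# Micro-CT types
# ---------------------------------------------------------------------------


@dataclass
class Volume3D:
    """3D intensity volume with isotropic voxels."""

    data: np.ndarray
    voxel_size_um: float = 26.5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be a 3D array")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")


@dataclass
class RegionMasks3D:
    """Kidney / medulla / cortex masks; cortex is kidney minus medulla."""

    kidney: np.ndarray
    medulla: np.ndarray
    cortex: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.kidney = np.asarray(self.kidney, dtype=bool)
        self.medulla = np.asarray(self.medulla, dtype=bool)
        if np.any(self.medulla & ~self.kidney):
            raise ValueError("medulla mask must be contained in the kidney mask")
        if self.cortex is None:
            self.cortex = self.kidney & ~self.medulla
        else:
            self.cortex = np.asarray(self.cortex, dtype=bool)
            if np.any(self.cortex != (self.kidney & ~self.medulla)):
                raise ValueError("cortex must equal kidney minus medulla exactly")


@dataclass
class RadiusMap:
    """Per-voxel local vessel radius (voxel units); zero outside vessels."""

    radius_vox: np.ndarray
    voxel_size_um: float = 26.5

    def __post_init__(self) -> None:
        self.radius_vox = np.asarray(self.radius_vox, dtype=float)

    @property
    def radius_um(self) -> np.ndarray:
        return self.radius_vox * self.voxel_size_um

    @property
    def mask(self) -> np.ndarray:
        return self.radius_vox > 0


@dataclass
class RegionDensityResult:
    """Small-vessel volume density inside one anatomical region.

    The density is the small-vessel voxel count divided by the region voxel
    count after removing large-vessel voxels from the region.
    """

    region: str
    small_vessel_voxels: int
    large_vessel_voxels_in_region: int
    region_voxels: int  # |region| before large-vessel removal
    radius_threshold_vox: float

    @property
    def denominator_voxels(self) -> int:
        return self.region_voxels - self.large_vessel_voxels_in_region

    @property
    def density(self) -> float:
        if self.denominator_voxels == 0:
            raise ZeroDivisionError("region is entirely large vessels")
        return self.small_vessel_voxels / self.denominator_voxels

    @property
    def density_percent(self) -> float:
        return self.density * 100.0
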