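"""End-to-end pipeline runners.

``run_srus_pipeline`` chains simulation → detection → motion estimation →
position correction → Kalman tracking → track accumulation → per-region
density and tortuosity, persisting every intermediate when an output
directory is configured.  ``run_uct_pipeline`` runs the micro-CT branch on
a rendered 3D phantom: kidney region growing, sparse-label interpolation,
vessel thresholding, local-radius estimation, small/large partition and
regional density.  Both are deterministic functions of the config
(including its seeds); a stage failure aborts with the stage name while
earlier intermediates stay on disk.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as uio
from .config import PipelineConfig
from .datatypes import REGION_LABELS, RegionDensityResult, Volume3D
from .detection import detect_stack
from .motion import correct_positions, estimate_motion
from .srus import accumulate_tracks, compute_patch_density, compute_tortuosity, render_srus_png
from .synthetic import (
    generate_vessel_tree,
    region_band_mask,
    render_uct_volume,
    simulate_mb_movie,
    sparsify_labels,
    subsample_tree,
    synthetic_kidney_masks,
)
from .tracking import track_microbubbles
from .uct import (
    compute_region_density,
    estimate_local_radius,
    interpolate_labels,
    partition_by_radius,
    segment_kidney,
    segment_vessels,
)

__all__ = ["run_srus_pipeline", "run_uct_pipeline"]

log = logging.getLogger("ulmvasc")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_srus_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run the full in vivo chain on a synthetic scene.

    Returns the per-region summary table (density %, mean distance-metric
    tortuosity, track counts) and, when ``config.output_dir`` is set,
    writes every intermediate (stacks, detections, motion, tracks, SRUS
    image, per-patch and per-track tables) plus the resolved config.
    """
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config_resolved.yaml")
    chash = config.config_hash

    sc = config.scene
    # the run seed governs every stochastic stage; the config object
    # itself is never mutated (its hash must stay stable)
    from dataclasses import replace

    acq = replace(config.acquisition, seed=config.seed)

    tree = _stage("simulate")(generate_vessel_tree)(
        n_root_vessels=sc.n_root_vessels,
        branching_depth=sc.branching_depth,
        tortuosity_amp=sc.tortuosity_amp,
        dims=2,
        seed=config.seed,
        extent_mm=sc.extent_mm,
    )
    if sc.keep_fraction < 1.0:
        tree = subsample_tree(tree, sc.keep_fraction, seed=config.seed + 1)
    contrast, bmode, truth = _stage("simulate")(simulate_mb_movie)(tree, acq)
    if out:
        uio.write_frame_stack(contrast, out / "contrast.tif")
        uio.write_frame_stack(bmode, out / "bmode.tif")

    detections = _stage("detect")(detect_stack)(
        contrast,
        rel_threshold=config.detection.rel_threshold,
        min_separation=config.detection.min_separation_mm,
        window_px=config.detection.window_px,
    )
    if out:
        uio.write_csv(uio.detections_to_frame(detections), out / "detections.csv")

    motion = _stage("motion")(estimate_motion)(
        bmode,
        reference_index=config.motion.reference_index,
        block_size=config.motion.block_size_mm,
        search_radius=config.motion.search_radius_mm,
    )
    if out:
        mdf = pd.DataFrame(
            {
                "frame": np.arange(motion.n_frames),
                "dx_mm": motion.displacements_mm[:, 0],
                "dz_mm": motion.displacements_mm[:, 1],
                "confidence": motion.confidence,
            }
        )
        uio.write_csv(mdf, out / "motion.csv")

    corrected = _stage("correct")(correct_positions)(detections, motion)
    if out:
        uio.write_csv(uio.detections_to_frame(corrected), out / "detections_corrected.csv")

    tracks = _stage("track")(track_microbubbles)(
        corrected, config.tracker, frame_rate=acq.frame_rate
    )
    if out:
        uio.write_csv(uio.tracks_to_frame(tracks), out / "tracks.csv")

    img = _stage("accumulate")(accumulate_tracks)(
        tracks, pixel_size=config.quant.sr_pixel_size_mm, extent_mm=sc.extent_mm
    )
    roi = region_band_mask(sc.extent_mm, config.quant.sr_pixel_size_mm)
    if out:
        render_srus_png(img, str(out / "srus.png"))

    rows = []
    patch_tables = []
    tort_tables = []
    for region in ("CO", "OM", "IM"):
        dres = _stage("density")(compute_patch_density)(
            img,
            roi,
            region,
            patch_side=config.quant.patch_side_mm,
            overlap=config.quant.overlap,
        )
        tres = _stage("tortuosity")(compute_tortuosity)(tracks, roi, region)
        rows.append(
            {
                "region": region,
                "n_tracks": len(tres.distance_metric),
                "n_patches": len(dres.patch_densities),
                "density_percent": dres.mean_density_percent,
                "mean_distance_metric": tres.mean_distance_metric,
                "n_zero_chord_excluded": tres.n_excluded_zero_chord,
                "config_hash": chash,
            }
        )
        patch_tables.append(
            pd.DataFrame(
                {
                    "region": region,
                    "center_x_mm": dres.patch_centers_mm[:, 0],
                    "center_z_mm": dres.patch_centers_mm[:, 1],
                    "density": dres.patch_densities,
                    "config_hash": chash,
                }
            )
        )
        tort_tables.append(
            pd.DataFrame(
                {
                    "region": region,
                    "track_id": tres.track_ids,
                    "distance_metric": tres.distance_metric,
                    "config_hash": chash,
                }
            )
        )

    summary = pd.DataFrame(rows)
    if out:
        uio.write_csv(pd.concat(patch_tables, ignore_index=True), out / "patch_density.csv")
        uio.write_csv(pd.concat(tort_tables, ignore_index=True), out / "tortuosity.csv")
        uio.write_csv(summary, out / "summary.csv")
    return summary


def run_uct_pipeline(config: PipelineConfig, tree=None) -> pd.DataFrame:
    """Run the micro-CT branch on a rendered phantom.

    A 3D tree (generated from ``config.scene`` unless supplied) is
    voxelized into a kidney-shaped phantom (parenchyma at
    ``kidney_intensity``, vessels at ``vessel_intensity``, additive
    noise); the full chain then recovers region masks and small-vessel
    densities.  Returns the per-region density table.
    """
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config_resolved.yaml")
    chash = config.config_hash
    u = config.uct
    sc = config.scene

    if tree is None:
        tree = _stage("uct-simulate")(generate_vessel_tree)(
            n_root_vessels=sc.n_root_vessels,
            branching_depth=sc.branching_depth,
            tortuosity_amp=sc.tortuosity_amp,
            dims=3,
            seed=config.seed,
            extent_mm=sc.extent_mm,
            root_radius_um=8.0 * u.voxel_size_um,
            slab_thickness_mm=sc.extent_mm / 4.0,
        )
    vol, true_radius = _stage("uct-simulate")(render_uct_volume)(
        tree, voxel_size_um=u.voxel_size_um, noise_sigma=0.0
    )

    # compose the phantom: parenchymal ellipsoid + bright vessels + noise
    kidney_true, medulla_true = synthetic_kidney_masks(vol.data.shape)
    rng = np.random.default_rng(config.seed + 7)
    data = np.where(vol.data > 0.5, u.vessel_intensity, 0.0)
    data = np.maximum(data, np.where(kidney_true, u.kidney_intensity, 0.0))
    data = data + rng.normal(0.0, u.noise_sigma, size=data.shape)
    phantom = Volume3D(data=data, voxel_size_um=u.voxel_size_um)
    if out:
        uio.write_volume(phantom, out / "phantom.nii.gz")

    seed_point = tuple(s // 2 for s in phantom.data.shape)
    kidney = _stage("segment-kidney")(segment_kidney)(
        phantom, seed_point, u.kidney_threshold
    )

    # medulla from sparse annotations, as an operator would provide them
    medulla_labels = medulla_true.astype(int)
    sparse = sparsify_labels(medulla_labels, stride=u.label_slice_stride, axis=0)
    dense = _stage("interp-labels")(interpolate_labels)(sparse, axis=0)
    medulla = (dense == 1) & kidney
    cortex = kidney & ~medulla

    vessels = _stage("segment-vessels")(segment_vessels)(
        phantom, kidney, u.vessel_threshold
    )
    rmap = _stage("radius")(estimate_local_radius)(vessels, voxel_size_um=u.voxel_size_um)
    if out:
        uio.write_volume(vessels.astype(float), out / "vessels.nii.gz", u.voxel_size_um)
        uio.write_radius_map(rmap, out / "radius_map.nii.gz")

    results: list[RegionDensityResult] = []
    for region, mask, thr in (
        ("cortex", cortex, u.cortex_radius_threshold_vox),
        ("medulla", medulla, u.medulla_radius_threshold_vox),
    ):
        small, large = partition_by_radius(rmap, thr)
        results.append(
            _stage("density")(compute_region_density)(
                small, large, mask, region=region, radius_threshold_vox=thr
            )
        )

    table = pd.DataFrame(
        {
            "region": [r.region for r in results],
            "radius_threshold_vox": [r.radius_threshold_vox for r in results],
            "radius_threshold_um": [r.radius_threshold_vox * u.voxel_size_um for r in results],
            "small_vessel_voxels": [r.small_vessel_voxels for r in results],
            "large_vessel_voxels": [r.large_vessel_voxels_in_region for r in results],
            "region_voxels": [r.region_voxels for r in results],
            "density_percent": [r.density_percent for r in results],
            "config_hash": chash,
        }
    )
    if out:
        uio.write_csv(table, out / "uct_density.csv")
    return table
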