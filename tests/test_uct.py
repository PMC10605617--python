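"""Micro-CT branch: segmentation, label interpolation, local thickness
(against a brute-force inscribed-sphere oracle), partition and density."""

import numpy as np
import pytest

from ulmvasc.datatypes import RadiusMap, RegionMasks3D, Volume3D
from ulmvasc.uct import (
    compute_region_density,
    estimate_local_radius,
    interpolate_labels,
    partition_by_radius,
    segment_kidney,
    segment_vessels,
)


def brute_force_local_thickness(mask):
    """Oracle: for every foreground voxel v, the radius of the largest
    sphere fully inside the foreground that contains v, by naive
    enumeration (no distance transform, no ordering tricks)."""
    mask = np.asarray(mask, dtype=bool)
    bg = np.argwhere(~mask).astype(float)
    fg = np.argwhere(mask).astype(float)
    # fit radius of a sphere centred at c = distance to nearest background
    fit = np.empty(len(fg))
    for i, c in enumerate(fg):
        fit[i] = np.sqrt(((bg - c) ** 2).sum(axis=1).min()) if len(bg) else np.inf
    out = np.zeros(mask.shape)
    for i, v in enumerate(fg):
        d2 = ((fg - v) ** 2).sum(axis=1)
        covered = d2 <= fit**2
        out[tuple(v.astype(int))] = fit[covered].max()
    return out


def _cylinder_mask(radius_vox, length=24, margin=None):
    margin = margin or int(np.ceil(radius_vox)) + 2
    n = 2 * margin + 1
    zz = np.zeros((length, n, n), dtype=bool)
    yy, xx = np.mgrid[0:n, 0:n]
    disk = (yy - margin) ** 2 + (xx - margin) ** 2 <= radius_vox**2
    zz[:] = disk
    return zz


class TestSegmentKidney:
    def _ellipsoid_volume(self, noise=0.05, seed=0):
        zz, yy, xx = np.mgrid[0:40, 0:40, 0:40]
        ell = ((zz - 20) / 16) ** 2 + ((yy - 20) / 13) ** 2 + ((xx - 20) / 11) ** 2 <= 1
        rng = np.random.default_rng(seed)
        data = np.where(ell, 1.0, 0.0) + rng.normal(0, noise, ell.shape)
        return Volume3D(data=data), ell

    def test_ellipsoid_recovered_up_to_closing_halo(self):
        vol, ell = self._ellipsoid_volume()
        mask = segment_kidney(vol, (20, 20, 20), threshold=0.5)
        missed = ell & ~mask
        extra = mask & ~ell
        assert missed.sum() / ell.sum() < 0.02
        assert extra.sum() / ell.sum() < 0.10  # closing halo only

    def test_threshold_above_max_rejected(self):
        vol, _ = self._ellipsoid_volume(noise=0.0)
        with pytest.raises(ValueError):
            segment_kidney(vol, (20, 20, 20), threshold=2.0)

    def test_connectivity_keeps_only_seeded_blob(self):
        data = np.zeros((30, 20, 20))
        data[2:8, 5:15, 5:15] = 1.0
        data[20:26, 5:15, 5:15] = 1.0
        vol = Volume3D(data=data)
        mask = segment_kidney(vol, (4, 10, 10), threshold=0.5, closing_radius_vox=0)
        assert mask[2:8, 5:15, 5:15].all()
        assert not mask[20:26].any()


class TestInterpolateLabels:
    def test_identical_disks_interpolate_to_same_disk(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disk = ((yy - 20) ** 2 + (xx - 20) ** 2 <= 100).astype(int)
        sparse = np.zeros((6, 40, 40), dtype=int)
        sparse[0] = disk
        sparse[5] = disk
        dense = interpolate_labels(sparse, axis=0)
        for k in range(1, 5):
            np.testing.assert_array_equal(dense[k], disk)

    def test_linear_growth_of_disk_radius(self):
        """Disk radius 10 on slice 0 and 20 on slice 10: the interpolated
        slice 5 carries a disk of radius ~15 (within one voxel)."""
        yy, xx = np.mgrid[0:64, 0:64]
        r2 = (yy - 32) ** 2 + (xx - 32) ** 2
        sparse = np.zeros((11, 64, 64), dtype=int)
        sparse[0] = (r2 <= 10**2).astype(int)
        sparse[10] = (r2 <= 20**2).astype(int)
        dense = interpolate_labels(sparse, axis=0)
        area = dense[5].sum()
        r_eff = np.sqrt(area / np.pi)
        assert r_eff == pytest.approx(15.0, abs=1.0)

    def test_fully_annotated_volume_is_identity(self):
        rng = np.random.default_rng(3)
        labels = (rng.random((5, 16, 16)) > 0.6).astype(int)
        labels[:, 0, 0] = 1  # every slice annotated
        dense = interpolate_labels(labels, axis=0)
        np.testing.assert_array_equal(dense, labels)

    def test_single_annotated_slice_warns(self):
        sparse = np.zeros((4, 16, 16), dtype=int)
        sparse[1, 5:10, 5:10] = 1
        with pytest.warns(UserWarning):
            interpolate_labels(sparse, axis=0)


class TestSegmentVessels:
    def test_noiseless_threshold_recovers_exact_foreground(self):
        mask = _cylinder_mask(4.0)
        vol = Volume3D(data=np.where(mask, 1.0, 0.0))
        kidney = np.ones(mask.shape, dtype=bool)
        np.testing.assert_array_equal(segment_vessels(vol, kidney, 0.5), mask)

    def test_threshold_above_vessel_intensity_empty(self):
        mask = _cylinder_mask(4.0)
        vol = Volume3D(data=np.where(mask, 0.8, 0.0))
        kidney = np.ones(mask.shape, dtype=bool)
        with pytest.raises(ValueError):
            segment_vessels(vol, kidney, 2.0)  # outside intensity range
        out = segment_vessels(vol, kidney, 0.8 - 1e-9)
        np.testing.assert_array_equal(out, mask)

    def test_vessel_count_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        mask = _cylinder_mask(4.0)
        vol = Volume3D(data=np.where(mask, 1.0, 0.0) + rng.normal(0, 0.1, mask.shape))
        kidney = np.ones(mask.shape, dtype=bool)
        counts = [
            segment_vessels(vol, kidney, thr).sum() for thr in (0.3, 0.5, 0.7, 0.9)
        ]
        assert np.all(np.diff(counts) <= 0)


class TestLocalRadius:
    @pytest.mark.parametrize("r", [3.0, 5.0, 8.0])
    def test_cylinder_against_brute_force_oracle(self, r):
        """Local thickness of a straight cylinder: mean absolute error vs
        the naive inscribed-sphere oracle <= 0.5 voxel away from the ends."""
        mask = _cylinder_mask(r, length=int(4 * r) + 8)
        rmap = estimate_local_radius(mask)
        oracle = brute_force_local_thickness(mask)
        k = int(np.ceil(r)) + 1
        interior = mask.copy()
        interior[:k] = False
        interior[-k:] = False
        mae = np.abs(rmap.radius_vox[interior] - oracle[interior]).mean()
        assert mae <= 0.5
        # and the estimate is close to the true tube radius in the core
        assert abs(rmap.radius_vox[interior].mean() - r) <= 1.0

    def test_single_voxel(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[3, 3, 3] = True
        rmap = estimate_local_radius(mask)
        assert rmap.radius_vox[3, 3, 3] == pytest.approx(1.0)
        assert rmap.radius_vox.sum() == pytest.approx(1.0)

    def test_fused_cylinders_bimodal(self):
        """Two touching cylinders (radius 3 and 8): the radius histogram
        shows modes near both radii."""
        big = _cylinder_mask(8.0, length=30)
        small = _cylinder_mask(3.0, length=30, margin=10)
        nz, ny, nx = big.shape
        vol = np.zeros((30, ny + 18, nx), dtype=bool)
        vol[:, :ny, :] = big
        vol[:, ny - 3 :, :] |= small[:, : vol.shape[1] - ny + 3, :]
        rmap = estimate_local_radius(vol)
        vals = rmap.radius_vox[vol]
        frac_small = ((vals > 2.0) & (vals < 4.5)).mean()
        frac_big = (vals > 6.5).mean()
        assert frac_small > 0.1
        assert frac_big > 0.3

    def test_empty_mask_gives_empty_map(self):
        rmap = estimate_local_radius(np.zeros((5, 5, 5), dtype=bool))
        assert rmap.radius_vox.sum() == 0

    def test_invariance_translation_and_axis_permutation(self):
        mask = _cylinder_mask(3.0, length=16)
        base = estimate_local_radius(mask).radius_vox
        shifted = np.roll(mask, 2, axis=1)
        np.testing.assert_allclose(
            estimate_local_radius(shifted).radius_vox, np.roll(base, 2, axis=1)
        )
        perm = np.transpose(mask, (1, 2, 0))
        np.testing.assert_allclose(
            estimate_local_radius(perm).radius_vox, np.transpose(base, (1, 2, 0))
        )


class TestPartitionAndDensity:
    def test_all_small_when_radii_below_threshold(self):
        mask = _cylinder_mask(3.0)
        rmap = estimate_local_radius(mask)
        small, large = partition_by_radius(rmap, 6.0)
        assert not large.any()
        np.testing.assert_array_equal(small, mask)

    def test_thick_cylinder_core_is_large(self):
        mask = _cylinder_mask(8.0, length=40)
        rmap = estimate_local_radius(mask)
        small, large = partition_by_radius(rmap, 6.0)
        core = mask[20, 10:13, 10:13]  # axis voxels mid-length
        assert large[20, 10:13, 10:13][core].all()

    def test_partition_property(self):
        mask = _cylinder_mask(5.0)
        rmap = estimate_local_radius(mask)
        small, large = partition_by_radius(rmap, 4.0)
        np.testing.assert_array_equal(small | large, mask)
        assert not (small & large).any()

    def test_region_masks_exact_set_relations(self):
        kidney = np.zeros((10, 10, 10), dtype=bool)
        kidney[2:8, 2:8, 2:8] = True
        medulla = np.zeros_like(kidney)
        medulla[4:6, 4:6, 4:6] = True
        rm = RegionMasks3D(kidney=kidney, medulla=medulla)
        assert not (rm.cortex & rm.medulla).any()
        np.testing.assert_array_equal(rm.cortex | rm.medulla, rm.kidney)
        with pytest.raises(ValueError):
            RegionMasks3D(kidney=medulla, medulla=kidney)

    def test_density_trivial_bounds(self):
        region = np.ones((6, 6, 6), dtype=bool)
        empty = np.zeros_like(region)
        res = compute_region_density(empty, empty, region)
        assert res.density == 0.0
        res = compute_region_density(region, empty, region)
        assert res.density == 1.0

    def test_cylinder_density_matches_analytic_volume(self):
        """One small cylinder of analytic volume v in a region of volume
        V, no large vessels: density v/V within 5%."""
        r, length = 4.0, 30
        mask = _cylinder_mask(r, length=length)
        region = np.ones(mask.shape, dtype=bool)
        rmap = estimate_local_radius(mask)
        small, large = partition_by_radius(rmap, 10.0)
        res = compute_region_density(small, large, region)
        analytic = np.pi * r**2 * length / region.sum()
        assert res.density == pytest.approx(analytic, rel=0.05)
        # reported counts are self-consistent
        assert res.small_vessel_voxels == (small & region).sum()
        assert res.denominator_voxels == region.sum() - (large & region).sum()

    def test_all_large_region_errors(self):
        region = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError):
            compute_region_density(np.zeros_like(region), region, region)
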