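"""Synthetic scene generator: geometry, ground truth, determinism."""

import numpy as np
import pytest
from scipy.integrate import quad

from ulmvasc import AcquisitionParams, generate_vessel_tree, simulate_mb_movie
from ulmvasc.synthetic import (
    analytic_region_density,
    render_uct_volume,
    subsample_tree,
    true_region_density,
)
from ulmvasc.datatypes import VesselSegment, VesselTree


class TestVesselTree:
    def test_single_straight_segment_has_unit_tortuosity(self):
        tree = generate_vessel_tree(1, 0, tortuosity_amp=0.0, dims=2, seed=7)
        assert len(tree.segments) == 1
        seg = tree.segments[0]
        # all points collinear with the chord
        chord = seg.points_mm[-1] - seg.points_mm[0]
        rel = seg.points_mm - seg.points_mm[0]
        cross = rel[:, 0] * chord[1] - rel[:, 1] * chord[0]
        assert np.allclose(cross, 0.0, atol=1e-12)
        assert seg.tortuosity == pytest.approx(1.0, abs=1e-12)

    def test_sinusoidal_tortuosity_matches_quadrature(self):
        """One full sine period of amplitude a over chord L: polyline
        tortuosity must match the analytic arc-length integral within 1%."""
        amp = 0.8
        tree = generate_vessel_tree(1, 0, tortuosity_amp=amp, dims=2, seed=7)
        seg = tree.segments[0]
        L = seg.chord_mm
        arc, _ = quad(
            lambda t: np.hypot(L, 2 * np.pi * amp * np.cos(2 * np.pi * t)), 0, 1
        )
        assert seg.tortuosity == pytest.approx(arc / L, rel=0.01)

    def test_determinism(self):
        a = generate_vessel_tree(5, 2, 0.3, dims=2, seed=11)
        b = generate_vessel_tree(5, 2, 0.3, dims=2, seed=11)
        assert len(a.segments) == len(b.segments)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.points_mm, sb.points_mm)

    def test_tortuosity_monotone_in_amplitude(self):
        amps = [0.0, 0.2, 0.5, 0.9]
        means = []
        for amp in amps:
            tree = generate_vessel_tree(6, 1, amp, dims=2, seed=2)
            means.append(np.mean([s.tortuosity for s in tree.segments]))
        assert means[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(means) > 0)

    def test_connectivity_children_start_on_parent_end(self):
        tree = generate_vessel_tree(2, 3, 0.4, dims=2, seed=9)
        endpoints = {tuple(np.round(s.points_mm[-1], 9)) for s in tree.segments}
        starts_at_root = 0
        for s in tree.segments:
            start = tuple(np.round(s.points_mm[0], 9))
            if start in endpoints:
                continue
            starts_at_root += 1  # must be a root entry point on z = 0
            assert s.points_mm[0][-1] == pytest.approx(0.0, abs=1e-9)
        assert starts_at_root == 2

    def test_tree_fits_bounding_box(self):
        tree = generate_vessel_tree(6, 2, 0.5, dims=3, seed=4)
        lo, hi = tree.bounding_box_mm[:, 0], tree.bounding_box_mm[:, 1]
        for s in tree.segments:
            assert np.all(s.points_mm >= lo - 1e-9)
            assert np.all(s.points_mm <= hi + 1e-9)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            generate_vessel_tree(0, 1)
        with pytest.raises(ValueError):
            generate_vessel_tree(1, 1, tortuosity_amp=-0.1)

    def test_subsample_keeps_requested_fraction(self):
        tree = generate_vessel_tree(10, 2, 0.0, seed=0)
        sub = subsample_tree(tree, 0.6, seed=1)
        assert len(sub.segments) == round(0.6 * len(tree.segments))

    def test_region_density_analytic_vs_rasterized(self):
        """Arc-length x width closed form vs rasterized-mask counting,
        within 5% when lumina span >= 2 grid pixels (the closed form
        ignores overlap, so the fixture uses parallel vessels)."""
        segs = [
            VesselSegment(
                points_mm=np.array([[x, 0.0], [x, 12.8]]),
                radius_um=150.0,
                flow_speed_mm_s=10.0,
            )
            for x in (2.0, 5.0, 8.0, 11.0)
        ]
        tree = VesselTree(segs, np.array([[0.0, 12.8], [0.0, 12.8]]))
        raster = true_region_density(tree, pixel_size=0.025)
        analytic = analytic_region_density(tree)
        for region in ("CO", "OM", "IM"):
            assert raster[region] == pytest.approx(analytic[region], rel=0.05)


class TestMicrobubbleMovie:
    def test_noiseless_blob_maxima_on_centreline(self):
        seg = VesselSegment(
            points_mm=np.array([[2.0, 6.0], [10.0, 6.0]]),
            radius_um=100.0,
            flow_speed_mm_s=10.0,
        )
        tree = VesselTree([seg], np.array([[0.0, 12.8], [0.0, 12.8]]))
        acq = AcquisitionParams(
            n_frames=30, noise_sigma=0.0, motion_amplitude=0.0,
            mb_influx_rate=20.0, seed=8,
        )
        contrast, _, truth = simulate_mb_movie(tree, acq)
        checked = 0
        for k in range(acq.n_frames):
            if not truth.true_detections[k] or contrast.frames[k].max() == 0:
                continue
            iz, ix = np.unravel_index(
                np.argmax(contrast.frames[k]), contrast.frames[k].shape
            )
            z_peak = (iz + 0.5) * acq.pixel_size
            assert abs(z_peak - 6.0) <= acq.pixel_size / 2
            checked += 1
        assert checked > 0

    def test_poisson_influx_count(self):
        tree = generate_vessel_tree(4, 1, 0.0, seed=1)
        rate, n_frames = 30.0, 550  # T = 10 s
        acq = AcquisitionParams(n_frames=n_frames, mb_influx_rate=rate, seed=123)
        _, _, truth = simulate_mb_movie(tree, acq)
        T = n_frames / acq.frame_rate
        n = len(truth.true_tracks)  # every bubble dwells >> one frame here
        assert abs(n - rate * T) <= 3 * np.sqrt(rate * T)

    def test_injected_motion_is_recorded_sinusoid(self):
        tree = generate_vessel_tree(3, 0, 0.0, seed=2)
        acq = AcquisitionParams(
            n_frames=40, motion_amplitude=0.3, motion_period=2.0, seed=3
        )
        _, bmode, truth = simulate_mb_movie(tree, acq)
        t = np.arange(acq.n_frames) / acq.frame_rate
        expected = 0.3 * np.sin(2 * np.pi * t / 2.0)
        np.testing.assert_allclose(truth.true_motion_mm[:, 1], expected, atol=1e-12)
        np.testing.assert_allclose(truth.true_motion_mm[:, 0], 0.0, atol=1e-9)
        assert bmode.n_frames == acq.n_frames

    def test_empty_tree_rejected(self):
        with pytest.raises(ValueError):
            simulate_mb_movie(
                VesselTree([], np.array([[0.0, 1.0], [0.0, 1.0]])),
                AcquisitionParams(n_frames=5),
            )

    def test_movie_determinism(self, default_tree):
        acq = AcquisitionParams(n_frames=20, seed=77)
        c1, b1, _ = simulate_mb_movie(default_tree, acq)
        c2, b2, _ = simulate_mb_movie(default_tree, acq)
        np.testing.assert_array_equal(c1.frames, c2.frames)
        np.testing.assert_array_equal(b1.frames, b2.frames)


class TestUCTRendering:
    def _cylinder_tree(self, radius_um, length_mm=1.5, voxel_um=26.5):
        pts = np.array([[0.75, 0.75, 0.0], [0.75, 0.75, length_mm]])
        seg = VesselSegment(points_mm=pts, radius_um=radius_um, flow_speed_mm_s=5.0)
        return VesselTree(
            [seg], np.array([[0.0, 1.5], [0.0, 1.5], [0.0, length_mm]])
        )

    def test_cylinder_voxel_count_matches_analytic_volume(self):
        voxel = 26.5
        r_vox = 5.0
        tree = self._cylinder_tree(radius_um=r_vox * voxel)
        vol, rmap = render_uct_volume(tree, voxel_size_um=voxel, noise_sigma=0.0)
        fg = vol.data > 0.5
        # compare the cap-free interior against the analytic cylinder volume
        zs = np.nonzero(fg.any(axis=(0, 1)))[0]
        k0, k1 = zs[0] + int(np.ceil(r_vox)) + 1, zs[-1] - int(np.ceil(r_vox)) - 1
        n_interior = int(fg[:, :, k0 : k1 + 1].sum())
        expected = np.pi * r_vox**2 * (k1 - k0 + 1)
        assert n_interior == pytest.approx(expected, rel=0.05)
        # radius field is exact on the foreground
        assert np.all(rmap.radius_vox[fg] == r_vox)

    def test_background_outside_tree(self):
        tree = self._cylinder_tree(radius_um=80.0)
        vol, _ = render_uct_volume(tree, noise_sigma=0.0)
        corner = vol.data[:3, :3, :3]
        assert np.all(corner == 0.0)

    def test_volume_determinism_with_noise(self):
        tree = self._cylinder_tree(radius_um=80.0)
        v1, _ = render_uct_volume(tree, noise_sigma=0.05, seed=9)
        v2, _ = render_uct_volume(tree, noise_sigma=0.05, seed=9)
        np.testing.assert_array_equal(v1.data, v2.data)

    def test_invalid_voxel_size(self):
        tree = self._cylinder_tree(radius_um=80.0)
        with pytest.raises(ValueError):
            render_uct_volume(tree, voxel_size_um=0.0)
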