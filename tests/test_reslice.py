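"""Curved reslicing: oracles against direct slicing and analytic fields."""

import numpy as np
import pytest

from octd.phantom import build_geometry
from octd.reslice import CenterlinePath, cross_section, longitudinal_reslice, trace_centerline
from octd.volume import OCTVolume

from conftest import make_compact_spec


def _random_volume(shape=(20, 16, 24), spacing=(5.0, 10.0, 8.0), seed=0):
    rng = np.random.default_rng(seed)
    return OCTVolume((rng.random(shape) * 255).astype(np.float32), spacing)


def _straight_path(spacing, length_um, axis=2, offset=(30.0, 40.0, 0.0), step=10.0):
    n = int(length_um / step) + 1
    pts = np.tile(np.asarray(offset, float), (n, 1))
    pts[:, axis] = offset[axis] + np.arange(n) * step
    return CenterlinePath(pts, np.arange(n) * step)


class TestLongitudinalReslice:
    def test_axis_aligned_curve_bit_matches_bscan(self):
        vol = _random_volume()
        dz, dy, dx = vol.spacing
        iy = 7
        curve = np.array([[iy * dy, 0.0], [iy * dy, (vol.shape[2] - 1) * dx]])
        out = longitudinal_reslice(vol, curve, step_um=dx)
        np.testing.assert_array_equal(out.pixels, vol.voxels[:, iy, :].astype(np.float64))

    def test_constant_volume_reslices_to_constant(self):
        vol = OCTVolume(np.full((10, 12, 14), 7.25, np.float32), (5.0, 5.0, 5.0))
        curve = np.array([[10.0, 5.0], [40.0, 60.0], [55.0, 30.0]])
        out = longitudinal_reslice(vol, curve)
        assert np.all(out.pixels == 7.25)

    def test_diagonal_reslice_of_linear_ramp_matches_closed_form(self):
        # volume value = y_um + x_um is linear, so bilinear sampling is exact:
        # along a 45-degree line the column value must equal y0+x0 + sqrt(2)*s
        shape, spacing = (4, 40, 40), (5.0, 10.0, 10.0)
        y = np.arange(shape[1]) * spacing[1]
        x = np.arange(shape[2]) * spacing[2]
        vol = OCTVolume(
            np.broadcast_to(y[:, None] + x[None, :], shape).astype(np.float64), spacing
        )
        start, end = np.array([30.0, 50.0]), np.array([280.0, 300.0])
        out = longitudinal_reslice(vol, np.stack([start, end]), step_um=10.0)
        s = np.arange(out.pixels.shape[1]) * out.pixel_spacing[1]
        expected = start.sum() + np.sqrt(2.0) * s
        np.testing.assert_allclose(out.pixels[0], expected, atol=1e-6)

    def test_closed_circle_column_count_tracks_circumference(self):
        vol = _random_volume(shape=(4, 60, 60), spacing=(5.0, 5.0, 5.0))
        theta = np.linspace(0, 2 * np.pi, 721)
        r = 80.0
        curve = np.column_stack([150 + r * np.sin(theta), 150 + r * np.cos(theta)])
        out = longitudinal_reslice(vol, curve, step_um=5.0)
        expected = round(2 * np.pi * r / 5.0)
        assert abs(out.pixels.shape[1] - expected) <= 1

    def test_curve_leaving_bounds_lists_offenders(self):
        vol = _random_volume()
        with pytest.raises(ValueError, match="bounds"):
            longitudinal_reslice(vol, np.array([[0.0, 0.0], [1e5, 0.0]]))


class TestCrossSection:
    def test_path_along_fast_axis_returns_axial_slow_plane(self):
        vol = _random_volume(spacing=(5.0, 10.0, 8.0))
        path = _straight_path(vol.spacing, 150.0, axis=2, offset=(0.0, 40.0, 0.0))
        out = cross_section(vol, path, s=48.0, halfwidth_um=150.0, step_um=10.0)
        # the section plane is axial x slow at fast index 48/8 = 6
        center_col = out.pixels.shape[1] // 2
        taken = out.pixels[:, center_col - 4 : center_col + 5]
        np.testing.assert_array_equal(taken, vol.voxels[:, 0:9, 6].astype(np.float64))

    def test_constant_volume_constant_inside(self):
        vol = OCTVolume(np.full((10, 20, 20), 3.5, np.float32), (5.0, 5.0, 5.0))
        path = _straight_path(vol.spacing, 80.0, axis=2, offset=(0.0, 50.0, 0.0))
        out = cross_section(vol, path, s=40.0, halfwidth_um=30.0)
        assert np.all(out.pixels[:, out.valid.all(axis=0)] == 3.5)

    def test_both_endpoints_are_valid_stations(self):
        vol = _random_volume()
        path = _straight_path(vol.spacing, 100.0)
        for s in (0.0, path.total_length):
            out = cross_section(vol, path, s, halfwidth_um=40.0)
            assert out.pixels.size

    def test_out_of_range_station_rejected(self):
        vol = _random_volume()
        path = _straight_path(vol.spacing, 100.0)
        with pytest.raises(ValueError, match="outside"):
            cross_section(vol, path, s=200.0, halfwidth_um=40.0)

    def test_out_of_volume_samples_filled_and_flagged(self):
        vol = _random_volume(shape=(6, 8, 30))
        path = _straight_path(vol.spacing, 100.0, offset=(0.0, 10.0, 0.0))
        out = cross_section(vol, path, s=50.0, halfwidth_um=500.0, fill=-1.0)
        assert not out.valid.all()
        assert np.all(out.pixels[~out.valid] == -1.0)


class TestTraceCenterline:
    def test_straight_cylinder_gives_collinear_axis_path(self):
        spacing = (5.0, 5.0, 5.0)
        mask = np.zeros((20, 20, 60), bool)
        zz, yy = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        disk = (zz - 10) ** 2 + (yy - 10) ** 2 <= 16
        mask[:, :, 5:55] = disk[:, :, None]
        path = trace_centerline(mask, spacing, (10, 10, 5))
        # collinear with the fast axis: no drift in z or y
        assert np.ptp(path.points[:, 0]) < 5.0
        assert np.ptp(path.points[:, 1]) < 5.0
        true_len = 49 * 5.0
        assert path.total_length == pytest.approx(true_len, abs=30.0)

    def test_seed_selects_one_of_two_tubes(self):
        mask = np.zeros((10, 30, 40), bool)
        mask[4:7, 5:8, 5:35] = True  # tube A
        mask[4:7, 20:23, 5:35] = True  # tube B
        path = trace_centerline(mask, (5.0, 5.0, 5.0), (5, 6, 6))
        assert np.all(path.points[:, 1] < 15 * 5.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            trace_centerline(np.zeros((5, 5, 5), bool), (1, 1, 1), (0, 0, 0))

    def test_distant_seed_rejected(self):
        mask = np.zeros((30, 30, 30), bool)
        mask[2:5, 2:5, 2:5] = True
        with pytest.raises(ValueError, match="voxels"):
            trace_centerline(mask, (1, 1, 1), (28, 28, 28))

    @pytest.mark.parametrize("method", ["shells", "skeleton"])
    def test_l_shaped_tube_path_length_within_five_percent(self, method):
        # thin L-tube: 300 µm vertical + 500 µm horizontal, radius 30 µm
        spacing = (5.0, 5.0, 5.0)
        mask = np.zeros((80, 40, 120), bool)
        zz, yy, xx = np.mgrid[:80, :40, :120]
        vert = ((yy - 20) ** 2 + (xx - 10) ** 2 <= 36) & (zz >= 5) & (zz <= 65)
        horiz = ((zz - 65) ** 2 + (yy - 20) ** 2 <= 36) & (xx >= 10) & (xx <= 110)
        mask = vert | horiz
        path = trace_centerline(mask, spacing, (5, 20, 10), method=method)
        assert path.total_length == pytest.approx(800.0, rel=0.05)

    def test_flask_phantom_path_length_near_analytic(self, compact_spec):
        # the flask is nearly as wide as it is deep, so the smooth centerline
        # rounds the elbow well inside the right-angle sum of segment lengths
        labels = build_geometry(compact_spec)
        mask = labels.mask("lumen")
        dz_c, dy, dx = compact_spec.spacing_corrected
        surf = compact_spec.conjunctiva_depth / compact_spec.refractive_index
        seed = (
            int(round((surf + 20) / dz_c)),
            int(round(compact_spec.punctum_yx[0] / dy)),
            int(round(compact_spec.punctum_yx[1] / dx)),
        )
        path = trace_centerline(mask, compact_spec.spacing_corrected, seed)
        analytic = compact_spec.vertical_length + compact_spec.horizontal_length
        assert path.total_length == pytest.approx(analytic, rel=0.15)

    def test_station_spacing_follows_arc_length(self):
        path = _straight_path((5, 5, 5), 2500.0, axis=1, offset=(10.0, 0.0, 30.0))
        p0, p1, p2 = (path.point_at(s) for s in (0.0, 1000.0, 2000.0))
        step = np.median(np.diff(path.arc_length))
        assert np.linalg.norm(p1 - p0) == pytest.approx(1000.0, abs=step / 2)
        assert np.linalg.norm(p2 - p1) == pytest.approx(1000.0, abs=step / 2)


class TestCenterlinePathValidation:
    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            CenterlinePath(np.array([[0.0, 0.0, 0.0]]), np.array([0.0]))

    def test_arc_length_strictly_increasing(self):
        pts = np.zeros((3, 3))
        with pytest.raises(ValueError, match="increasing"):
            CenterlinePath(pts, np.array([0.0, 1.0, 1.0]))
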