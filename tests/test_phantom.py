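"""Phantom geometry, kinetics forward model and rendering contracts."""

import numpy as np
import pytest

from octd.phantom import LABELS, PhantomSpec, build_geometry, kinetics_curve, render_frame, generate_series

from conftest import make_compact_spec, make_tiny_spec


class TestKineticsCurve:
    def test_baseline_at_time_zero(self):
        spec = make_tiny_spec()
        assert kinetics_curve(0.0, spec) == spec.lumen_baseline_intensity

    def test_peak_at_peak_time(self):
        spec = make_tiny_spec()
        assert kinetics_curve(spec.peak_time, spec) == spec.contrast_peak_intensity

    def test_half_amplitude_one_half_life_after_peak(self):
        spec = make_tiny_spec(washout_half_life=3.5)
        t = spec.peak_time + spec.washout_half_life
        expected = spec.lumen_baseline_intensity + (
            spec.contrast_peak_intensity - spec.lumen_baseline_intensity
        ) / 2
        assert kinetics_curve(t, spec) == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kinetics_curve(-0.1, make_tiny_spec())


class TestGeometry:
    def test_horizontal_lumen_axial_thickness_matches_spec(self):
        spec = make_compact_spec()
        labels = build_geometry(spec)
        dz_c, dy, dx = spec.spacing_corrected
        iy = int(round(spec.punctum_yx[0] / dy))
        ix = int(round((spec.punctum_yx[1] + 0.6 * spec.horizontal_length) / dx))
        col = labels.mask("lumen")[:, iy, ix]
        n_vox = int(col.sum())
        assert abs(n_vox - spec.horizontal_ap_height / dz_c) <= 1

    def test_open_punctum_reaches_the_surface(self):
        spec = make_compact_spec()
        labels = build_geometry(spec)
        dz_air = spec.spacing_air[0]
        surf_row = int(np.ceil(spec.conjunctiva_depth / dz_air))
        assert labels.mask("lumen")[surf_row].any()

    def test_punctal_mode_buries_lumen_at_requested_depth(self):
        spec = make_compact_spec(obstruction_mode="punctal", blind_extremity_depth=259.0)
        labels = build_geometry(spec)
        dz_c = spec.spacing_corrected[0]
        surf_um = spec.conjunctiva_depth / spec.refractive_index
        iz = np.nonzero(labels.mask("lumen").any(axis=(1, 2)))[0].min()
        depth = iz * dz_c - surf_um
        assert abs(depth - 259.0) <= dz_c

    def test_lumen_enclosed_by_epithelium_except_at_opening(self):
        from scipy import ndimage

        spec = make_compact_spec(obstruction_mode="punctal")
        labels = build_geometry(spec)
        lumen = labels.mask("lumen")
        shell = ndimage.binary_dilation(
            lumen, ndimage.generate_binary_structure(3, 1)
        ) & ~lumen
        assert np.all(labels.labels[shell] == LABELS["epithelium"])

    def test_canalicular_mode_truncates_and_tapers(self):
        spec = make_compact_spec()
        trunc = make_compact_spec(obstruction_mode="canalicular")
        full = build_geometry(spec).mask("lumen")
        cut = build_geometry(trunc).mask("lumen")
        x_full = np.nonzero(full.any(axis=(0, 1)))[0].max()
        x_cut = np.nonzero(cut.any(axis=(0, 1)))[0].max()
        assert x_cut < x_full
        # per-B-scan lumen width shrinks toward the obstruction
        widths = cut.sum(axis=(0, 1)).astype(float)
        tail = widths[x_cut - 10 : x_cut + 1]
        assert tail[-1] < tail[0]

    def test_oversized_geometry_rejected_with_sizing_message(self):
        with pytest.raises(ValueError, match="does not fit"):
            build_geometry(make_tiny_spec(horizontal_length=5000.0))


class TestRendering:
    def test_noiseless_limit_returns_label_means(self):
        spec = make_tiny_spec(speckle_shape=float("inf"), air_noise_sigma=0.0)
        labels = build_geometry(spec)
        frame = render_frame(labels, spec, t=1.0, seed=0)
        assert np.all(frame.voxels[labels.mask("tissue")] == spec.tissue_mean_intensity)
        assert np.all(
            frame.voxels[labels.mask("lumen")] == spec.contrast_peak_intensity
        )

    def test_lumen_mean_near_peak_value_under_speckle(self):
        spec = make_compact_spec()
        labels = build_geometry(spec)
        frame = render_frame(labels, spec, t=1.0, seed=1)
        lumen = labels.mask("lumen")
        assert lumen.sum() >= 10_000
        mean = frame.voxels[lumen].mean()
        assert mean == pytest.approx(spec.contrast_peak_intensity, rel=0.02)

    def test_equal_seeds_render_identically(self):
        spec = make_tiny_spec()
        labels = build_geometry(spec)
        a = render_frame(labels, spec, t=2.0, seed=7)
        b = render_frame(labels, spec, t=2.0, seed=7)
        np.testing.assert_array_equal(a.voxels, b.voxels)


class TestSeries:
    def test_eleven_minutewise_frames_on_shared_grid(self):
        spec = make_tiny_spec()
        series, labels = generate_series(spec)
        assert len(series) == 11
        assert series.timestamps_min == list(range(11))
        assert all(f.shape == labels.shape for f in series.frames)
        assert all(f.spacing == spec.spacing_air for f in series.frames)

    def test_lumen_intensity_peaks_at_one_minute(self):
        spec = make_tiny_spec()
        series, labels = generate_series(spec)
        lumen = labels.mask("lumen")
        means = [f.voxels[lumen].mean() for f in series.frames]
        assert int(np.argmax(means)) == 1

    def test_series_deterministic_for_fixed_spec(self):
        spec = make_tiny_spec(rng_seed=42)
        a, _ = generate_series(spec)
        b, _ = generate_series(spec)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.voxels, fb.voxels)

    def test_save_series_layout(self, tmp_path):
        import json

        from octd.phantom import save_series

        spec = make_tiny_spec()
        series, labels = generate_series(spec)
        out = save_series(series, labels, spec, tmp_path / "run")
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["files"][0] == "frame_t00.tif"
        assert len(manifest["files"]) == 11
        assert (out / "labels.tif").exists()


class TestSpecValidation:
    def test_air_must_be_darker_than_tissue(self):
        with pytest.raises(ValueError, match="darker"):
            make_tiny_spec(air_mean_intensity=200.0)

    def test_contrast_peak_above_baseline(self):
        with pytest.raises(ValueError, match="peak"):
            make_tiny_spec(contrast_peak_intensity=5.0)

    def test_positive_half_life_required(self):
        with pytest.raises(ValueError):
            make_tiny_spec(washout_half_life=0.0)
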