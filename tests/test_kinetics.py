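"""ROI means, time-intensity curves and the washout half-life statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octd.kinetics import (
    ROISpec,
    TimeIntensityCurve,
    build_curve,
    cohort_summary,
    compute_t_half,
    roi_mean,
    WashoutResult,
)
from octd.phantom import generate_series
from octd.volume import OCTVolume, VolumeSeries, correct_refraction

from conftest import make_tiny_spec


class TestRoiMean:
    def test_constant_image_returns_constant(self):
        img = np.full((30, 30), 7.0)
        roi = ROISpec(((100.0, 100.0, 40.0),))
        assert roi_mean(img, (10.0, 10.0), roi) == 7.0

    def test_overlapping_circles_do_not_double_count(self):
        rng = np.random.default_rng(0)
        img = rng.random((40, 40))
        one = ROISpec(((150.0, 150.0, 80.0),))
        two = ROISpec(((150.0, 150.0, 80.0), (160.0, 150.0, 60.0)))
        a = roi_mean(img, (10.0, 10.0), one)
        b = roi_mean(img, (10.0, 10.0), two)
        # the second circle lies inside the first: identical pixel set
        assert a == b

    def test_minimum_lumen_area_rule(self):
        with pytest.raises(ValueError, match="µm²"):
            ROISpec(((50.0, 50.0, 5.0),), target="lumen")  # 78.5 µm² alone
        ROISpec(((50.0, 50.0, 5.0), (80.0, 50.0, 5.0)), target="lumen")  # two accepted
        ROISpec(((50.0, 50.0, 5.0),), target="air")  # air has no area floor

    def test_roi_outside_image_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError, match="outside"):
            roi_mean(img, (10.0, 10.0), ROISpec(((500.0, 500.0, 30.0),)))


class TestBuildCurve:
    def test_phantom_curve_peaks_at_one_minute(self):
        spec = make_tiny_spec()
        series, _ = generate_series(spec)
        corrected = VolumeSeries(
            [correct_refraction(f, spec.refractive_index) for f in series.frames],
            series.timestamps_min,
        )
        dz_c, dy, dx = spec.spacing_corrected
        z_surf = spec.conjunctiva_depth / spec.refractive_index
        lumen = ROISpec(
            ((z_surf + spec.vertical_ap_diameter / 2, spec.punctum_yx[0], 60.0),)
        )
        air = ROISpec(((60.0, spec.punctum_yx[0], 60.0),), target="air")
        ix = int(round(spec.punctum_yx[1] / dx))
        curve = build_curve(corrected, lumen, air, section_axis="fast", section_index=ix)
        assert int(curve.times_min[np.argmax(curve.values)]) == 1

    def test_background_subtraction_cancels_global_offsets(self):
        spec = make_tiny_spec(speckle_shape=float("inf"), air_noise_sigma=0.0)
        series, _ = generate_series(spec)
        dz_c, dy, dx = spec.spacing_corrected
        frames_shifted = [
            OCTVolume(f.voxels + 25.0, f.spacing, f.medium, f.metadata)
            for f in series.frames
        ]
        shifted = VolumeSeries(frames_shifted, series.timestamps_min)
        z = spec.conjunctiva_depth + spec.refractive_index * spec.vertical_ap_diameter / 2
        lumen = ROISpec(((z, spec.punctum_yx[0], 60.0),))
        air = ROISpec(((60.0, spec.punctum_yx[0], 60.0),), target="air")
        ix = int(round(spec.punctum_yx[1] / dx))
        c0 = build_curve(series, lumen, air, section_axis="fast", section_index=ix)
        c1 = build_curve(shifted, lumen, air, section_axis="fast", section_index=ix)
        np.testing.assert_allclose(c0.values, c1.values, atol=1e-4)


class TestComputeTHalf:
    def test_worked_example_reads_definition_directly(self):
        c = TimeIntensityCurve(np.arange(6.0), np.array([0, 10, 8, 6, 4, 3.0]))
        r = compute_t_half(c)
        assert (r.t_peak_min, r.t_cross_min, r.t_half_min) == (1.0, 4.0, 3.0)
        assert not r.censored

    def test_immediate_crossing(self):
        c = TimeIntensityCurve(np.arange(3.0), np.array([0.0, 10.0, 4.0]))
        assert compute_t_half(c).t_half_min == 1.0

    def test_exact_half_does_not_cross(self):
        c = TimeIntensityCurve(np.arange(4.0), np.array([0.0, 10.0, 5.0, 5.0]))
        assert compute_t_half(c).censored

    def test_all_equal_curve_is_censored(self):
        c = TimeIntensityCurve(np.arange(5.0), np.full(5, 3.0))
        r = compute_t_half(c)
        assert r.censored and r.t_half_min is None

    def test_earliest_tie_wins_the_peak(self):
        c = TimeIntensityCurve(np.arange(6.0), np.array([0, 9, 9, 9, 4, 1.0]))
        assert compute_t_half(c).t_peak_min == 1.0

    @pytest.mark.parametrize("h", [2.5, 3.7, 5.25, 6.5, 8.75])
    def test_noninteger_half_life_quantizes_into_h_h_plus_one(self, h):
        t = np.arange(11.0)
        v = np.where(t <= 1, 100.0 * t, 100.0 * 2 ** (-(t - 1) / h))
        r = compute_t_half(TimeIntensityCurve(t, v))
        assert h <= r.t_half_min < h + 1

    def test_integer_half_life_crosses_one_minute_late(self):
        # exact half at the h-minute offset is not "less than half":
        # the strict rule pushes the crossing to the next sample
        h = 3
        t = np.arange(11.0)
        v = np.where(t <= 1, 100.0 * t, 100.0 * 2 ** (-(t - 1) / h))
        assert compute_t_half(TimeIntensityCurve(t, v)).t_half_min == h + 1

    def test_true_half_life_2p5_reads_3_minutes(self):
        t = np.arange(11.0)
        v = np.where(t <= 1, 100.0 * t, 100.0 * 2 ** (-(t - 1) / 2.5))
        assert compute_t_half(TimeIntensityCurve(t, v)).t_half_min == 3.0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1e6, allow_nan=False), min_size=2, max_size=24)
    )
    def test_crossing_contract_on_arbitrary_curves(self, values):
        c = TimeIntensityCurve(np.arange(len(values), dtype=float), np.array(values))
        r = compute_t_half(c)
        if not r.censored:
            assert r.t_half_min > 0
            i = int(np.nonzero(c.times_min == r.t_cross_min)[0][0])
            assert c.values[i] < r.peak_value / 2
            # nothing between peak and crossing is below half-peak
            j = int(np.nonzero(c.times_min == r.t_peak_min)[0][0])
            assert np.all(c.values[j + 1 : i] >= r.peak_value / 2)


class TestCohortSummary:
    def test_two_value_mean_and_sd(self):
        res = [
            WashoutResult(1, 10, 7, 6.0, False),
            WashoutResult(1, 10, 8, 7.0, False),
        ]
        s = cohort_summary(res)
        assert s.mean_min == 6.5
        assert s.sd_min == pytest.approx(0.7071, abs=1e-3)

    def test_censored_counted_not_imputed(self):
        res = [WashoutResult(1, 10, None, None, True)] + [
            WashoutResult(1, 10, 5, 4.0, False)
        ] * 9
        s = cohort_summary(res)
        assert s.n_used == 9 and s.n_censored == 1

    def test_all_censored_is_an_error(self):
        with pytest.raises(ValueError, match="censored"):
            cohort_summary([WashoutResult(1, 10, None, None, True)])
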