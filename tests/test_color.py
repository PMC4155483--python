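"""Camera rendering, hue closed forms and the H-parameter monitors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psimon import (BUFFER, SILICON, CameraModel, LayerStack, PorousLayer,
                    ReflectanceSpectrum, RGBSeries, UniformLayer,
                    DegradationTrajectory, color_rate, compute_h_parameter,
                    compute_hue, default_wavelength_grid,
                    minmax_normalize_channels, reference_balance, render_rgb,
                    rugate_period_for_peak, simulate_degradation_series,
                    simulate_reflectance)

LAM = default_wavelength_grid()


def flat_reflector(r=1.0):
    return ReflectanceSpectrum(LAM, np.full(LAM.size, r))


class TestComputeHue:
    @pytest.mark.parametrize("rgb, expected", [
        ((255, 0, 0), 0.0),
        ((0, 255, 0), 1.0 / 3.0),
        ((0, 0, 255), 2.0 / 3.0),
        ((255, 255, 0), 1.0 / 6.0),
        ((255, 51, 0), 0.2 / 6.0),  # the camera's initial deep red
    ])
    def test_closed_forms(self, rgb, expected):
        assert compute_hue(np.array(rgb, float)) == pytest.approx(expected,
                                                                  abs=1e-9)

    @pytest.mark.parametrize("gray", [0.0, 127.5, 255.0])
    def test_achromatic_is_undefined(self, gray):
        assert math.isnan(compute_hue(np.full(3, gray)))

    @pytest.mark.parametrize("k", [0.25, 0.5, 2.0])
    def test_intensity_scaling_invariance(self, k):
        rgb = np.array([120.0, 70.0, 30.0])
        assert compute_hue(k * rgb) == pytest.approx(compute_hue(rgb),
                                                     abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.tuples(*[st.floats(0, 255)] * 3))
    def test_hue_range(self, rgb):
        h = compute_hue(np.array(rgb))
        assert math.isnan(h) or 0.0 <= h < 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_hue(np.array([300.0, 0.0, 0.0]))


class TestRenderRgb:
    def test_flat_reflector_is_neutral_with_balanced_camera(self):
        rgb = render_rgb(flat_reflector(), CameraModel(), quantize=False)
        assert rgb[0] == pytest.approx(rgb[1], rel=1e-9)
        assert rgb[1] == pytest.approx(rgb[2], rel=1e-9)

    def test_red_band_orders_channels(self):
        r = 0.02 + 0.9 * np.exp(-0.5 * ((LAM - 640.0) / 10.0) ** 2)
        rgb = render_rgb(ReflectanceSpectrum(LAM, r), CameraModel(),
                         quantize=False)
        assert rgb[0] > rgb[1] > rgb[2]

    def test_bare_si_under_tungsten_without_balance_is_red_rich(self):
        """The lamp reflection off the exposed wafer has a yellow cast."""
        spec = simulate_reflectance(
            LayerStack([UniformLayer(BUFFER, 0.0)], substrate=SILICON,
                       ambient=BUFFER))
        rgb = render_rgb(spec, CameraModel(white_balance="none"),
                         quantize=False)
        assert rgb[0] > rgb[1] > rgb[2]
        hue = compute_hue(rgb)
        assert 0.0 < hue < 1.0 / 6.0  # red-to-yellow sector

    def test_black_spectrum_renders_black(self):
        rgb = render_rgb(flat_reflector(0.0), CameraModel())
        assert tuple(rgb) == (0.0, 0.0, 0.0)

    def test_quantized_output_is_integer_8bit(self):
        rgb = render_rgb(flat_reflector(0.5), CameraModel())
        assert np.all(rgb == np.round(rgb))
        assert np.all((rgb >= 0) & (rgb <= 255))


class TestReferenceBalance:
    def test_gray_reference_is_identity(self):
        rgb = np.array([120.0, 30.0, 88.0])
        out = reference_balance(rgb, np.array([200.0, 200.0, 200.0]))
        np.testing.assert_allclose(out, rgb)

    def test_sample_equal_to_reference_becomes_gray(self):
        out = reference_balance(np.array([200.0, 100.0, 100.0]),
                                np.array([200.0, 100.0, 100.0]))
        assert out[0] == out[1] == out[2]

    def test_common_scaling_equivariance(self):
        """Dimming scene and reference together rescales the output but
        leaves its chromaticity (hue) untouched."""
        rgb = np.array([90.0, 60.0, 30.0])
        ref = np.array([180.0, 120.0, 100.0])
        half = reference_balance(0.5 * rgb, 0.5 * ref)
        full = reference_balance(rgb, ref)
        np.testing.assert_allclose(2.0 * half, full)
        assert compute_hue(half) == pytest.approx(compute_hue(full))

    def test_zero_reference_channel_rejected(self):
        with pytest.raises(ValueError):
            reference_balance(np.array([10.0, 10.0, 10.0]),
                              np.array([100.0, 0.0, 100.0]))


class TestMinMaxNormalization:
    def test_channel_extrema_map_to_0_and_255(self):
        t = np.arange(4.0)
        rgb = np.column_stack([np.array([50.0, 100.0, 150.0, 75.0]),
                               np.full(4, 10.0), np.arange(4.0) * 10])
        out = minmax_normalize_channels(RGBSeries(t, rgb))
        assert out.rgb[:, 0].min() == 0.0
        assert out.rgb[:, 0].max() == 255.0

    def test_constant_channel_maps_to_midscale(self):
        t = np.arange(3.0)
        rgb = np.column_stack([np.full(3, 42.0), np.arange(3.0) * 5,
                               np.arange(3.0) * 7])
        out = minmax_normalize_channels(RGBSeries(t, rgb))
        np.testing.assert_allclose(out.rgb[:, 0], 127.5)

    def test_affine_invariance(self):
        t = np.arange(5.0)
        x = np.column_stack([np.sin(t) * 20 + 100, t * 3 + 7,
                             np.cos(t) * 15 + 60])
        a, b = 0.4, 12.0
        out1 = minmax_normalize_channels(RGBSeries(t, x))
        out2 = minmax_normalize_channels(RGBSeries(t, a * x + b))
        np.testing.assert_allclose(out1.rgb, out2.rgb, atol=1e-9)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize_channels(RGBSeries(np.array([0.0]),
                                                np.array([[1.0, 2.0, 3.0]])))


class TestHParameter:
    @staticmethod
    def _red_to_green_sweep(n=11):
        """Rendered narrow band sweeping 640 -> 540 nm (red to green)."""
        cam = CameraModel()
        centers = np.linspace(640.0, 540.0, n)
        rgb = np.array([render_rgb(ReflectanceSpectrum(
            LAM, 0.05 + 0.85 * np.exp(-0.5 * ((LAM - c) / 12.0) ** 2)),
            cam, quantize=False) for c in centers])
        return RGBSeries(np.arange(float(n)), rgb)

    def test_red_to_green_ramp_increases(self):
        hs = compute_h_parameter(self._red_to_green_sweep())
        assert np.all(np.diff(hs.h_param) > 0)

    def test_h_norm_anchors(self):
        hs = compute_h_parameter(self._red_to_green_sweep())
        assert hs.h_norm[0] == 0.0
        assert np.nanmax(hs.h_norm) == pytest.approx(1.0)
        assert hs.h_norm[np.nanargmax(hs.h_param)] == pytest.approx(1.0)

    def test_achromatic_series_warns_and_is_missing(self):
        t = np.arange(3.0)
        rgb = np.full((3, 3), 99.0)
        with pytest.warns(UserWarning):
            hs = compute_h_parameter(RGBSeries(t, rgb))
        assert np.all(np.isnan(hs.h_param))

    def test_color_rate_on_linear_h_norm_is_exact(self):
        from psimon import HueSeries
        t = 5.0 * np.arange(7.0)
        h_norm = 0.02 * t
        hs = HueSeries(t, np.full(7, 0.05), np.full(7, 0.1), h_norm)
        fit = color_rate(hs, (0.0, 30.0))
        assert fit.slope == pytest.approx(0.02, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_empty_window_rejected(self):
        hs = compute_h_parameter(self._red_to_green_sweep())
        with pytest.raises(ValueError):
            color_rate(hs, (20.0, 30.0))


def _unimodal(x, tol=3.0, win=3):
    """At most one direction change after smoothing; moves below ``tol``
    8-bit counts are ignored (fringe ripple)."""
    xs = np.convolve(x, np.ones(win) / win, mode="valid")
    d = np.diff(xs)
    sign = np.sign(d[np.abs(d) > tol])
    return np.sum(np.diff(sign) != 0) <= 1


def _unwrap_hue(h):
    """Lift the circular hue onto the line (shortest-arc increments)."""
    d = (np.diff(h) + 0.5) % 1.0 - 0.5
    return np.concatenate([[h[0]], h[0] + np.cumsum(d)])


def test_h_parameter_monotone_on_blue_shift_trajectories():
    """Monotone pore-wall dissolution with orderly channel evolution gives
    a monotone H parameter, across >= 10 random film/rate configurations."""
    rng = np.random.default_rng(2026)
    checked = 0
    for _ in range(14):
        p0 = rng.uniform(0.48, 0.60)
        amp = rng.uniform(0.010, 0.016)
        peak = rng.uniform(575.0, 605.0)
        t_d = rng.uniform(90.0, 110.0)
        period = rugate_period_for_peak(peak, p0, SILICON, BUFFER)
        layer = PorousLayer.rugate(p0, 22.8, amp, period, SILICON, BUFFER)
        stack = LayerStack([layer], substrate=SILICON, ambient=BUFFER)
        traj = DegradationTrajectory(porosity_rate=(1 - p0) / t_d,
                                     t_grid=np.arange(0.0, 151.0, 10.0))
        series = simulate_degradation_series(stack, traj)
        cam = CameraModel(white_balance="none")
        rgb = np.array([render_rgb(s, cam, quantize=False)
                        for _, s in series])
        rgbs = RGBSeries(traj.t_grid, rgb)
        if not all(_unimodal(rgb[:, ch]) for ch in range(3)):
            continue
        hs = compute_h_parameter(rgbs)
        assert np.all(np.diff(_unwrap_hue(hs.h_param)) >= -1e-9)
        checked += 1
    assert checked >= 10


def test_full_degradation_hue_contrast(full_run):
    """Raw hue rises while the film shifts blue and falls once the bare
    wafer's lamp reflection dominates; the H parameter keeps increasing."""
    _, _, _, hue_series = full_run
    hue = hue_series.hue
    finite = np.isfinite(hue)
    assert finite.all()
    peak_at = int(np.argmax(hue))
    assert hue[peak_at] > hue[0]          # rises from the initial red
    assert hue[-1] < hue[peak_at]         # falls after dissolution
    assert 0 < peak_at < hue.size - 1
    assert np.all(np.diff(hue_series.h_param) >= -1e-12)
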