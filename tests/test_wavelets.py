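"""Wavelet engine: mother wavelets, boundary extension, CWT rows/scalograms."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wavecal as wc
from wavecal.wavelets import kernel_radius


def dense_cwt_row(values, wavelet, scale, mode="symmetric"):
    """Direct O(n^2) discretisation of the CWT integral (test oracle)."""
    w = wc.get_wavelet(wavelet) if isinstance(wavelet, str) else wavelet
    radius = kernel_radius(w, scale)
    ext = wc.boundary_extend(np.asarray(values, float), radius, mode)
    idx = np.arange(ext.size) - radius  # absolute channel of each extended sample
    out = np.empty(len(values))
    for b in range(len(values)):
        out[b] = np.sum(ext * w((idx - b) / scale)) / math.sqrt(scale)
    return out


class TestMotherWavelets:
    def test_unknown_name_raises(self):
        with pytest.raises(wc.UnsupportedWaveletError):
            wc.get_wavelet("morl7")

    @pytest.mark.parametrize("name", wc.WAVELET_NAMES)
    def test_admissibility_zero_mean(self, name):
        w = wc.get_wavelet(name)
        x = np.linspace(w.support[0], w.support[1], 100001)
        dx = x[1] - x[0]
        psi = w(x)
        assert abs(psi.sum() * dx) < 1e-6 * np.abs(psi).sum() * dx

    @pytest.mark.parametrize("name", wc.WAVELET_NAMES)
    def test_effectively_zero_outside_dilated_support(self, name):
        w = wc.get_wavelet(name)
        vals = wc.evaluate_wavelet(w, 5.0, [5 * w.radius * 1.5, -5 * w.radius * 2.0])
        assert np.all(np.abs(vals) < 1e-9)

    def test_dilation_stretches_support(self):
        # the Mexican hat becomes "shorter and wider" as the scale grows
        w = wc.get_wavelet("mexh")
        x = np.linspace(-400, 400, 80001)

        def effective_width(scale):
            vals = np.abs(wc.evaluate_wavelet(w, scale, x))
            return np.ptp(x[vals > 1e-3 * vals.max()])

        base = effective_width(1)
        for a in (10, 40):
            assert effective_width(a) / base == pytest.approx(a, rel=0.02)

    def test_haar_antisymmetric_and_zero_mean(self):
        w = wc.get_wavelet("haar")
        grid = np.array([-0.4, -0.1, 0.1, 0.4])
        np.testing.assert_array_equal(w(grid), [1.0, 1.0, -1.0, -1.0])
        assert w(np.array([0.0]))[0] == 0.0  # midpoint convention at the jump
        fine = np.linspace(-0.5, 0.5, 2001)
        assert abs(w(fine).sum()) <= 1.0

    def test_mexh_closed_form_at_origin(self):
        # standard L2-normalised second-derivative-of-Gaussian value at x=0
        expected = 2.0 / (math.sqrt(3.0) * math.pi**0.25)
        assert wc.evaluate_wavelet("mexh", 1.0, [0.0])[0] == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            wc.evaluate_wavelet("mexh", 0.0, [0.0])
        with pytest.raises(ValueError):
            wc.cwt_row(np.ones(16), "mexh", -3)


class TestBoundaryExtend:
    def test_symmetric_half_point_reflection(self):
        out = wc.boundary_extend(np.array([1.0, 2.0, 3.0]), 2, "symmetric")
        np.testing.assert_array_equal(out, [2, 1, 1, 2, 3, 3, 2])

    @pytest.mark.parametrize("mode", ["symmetric", "reflect", "zero"])
    def test_constant_signal_interior_preserved(self, mode):
        sig = np.full(10, 4.2)
        out = wc.boundary_extend(sig, 3, mode)
        assert out.size == 16
        np.testing.assert_array_equal(out[3:-3], sig)
        if mode != "zero":
            np.testing.assert_array_equal(out, np.full(16, 4.2))

    def test_round_trip_crop_identity(self, rng):
        sig = rng.normal(size=17)
        for mode in ("symmetric", "reflect", "zero"):
            out = wc.boundary_extend(sig, 5, mode)
            np.testing.assert_array_equal(out[5:-5], sig)

    def test_signal_vector_axis_extrapolated(self):
        sv = wc.SignalVector(np.array([10.0, 11.0, 12.0]), np.array([1.0, 2.0, 3.0]))
        out = wc.boundary_extend(sv, 2, "symmetric")
        np.testing.assert_allclose(out.channel_axis, np.arange(8.0, 15.0))

    def test_invalid_half_width(self):
        with pytest.raises(ValueError):
            wc.boundary_extend(np.ones(5), 0)


class TestSignalVector:
    def test_validation(self):
        with pytest.raises(ValueError):
            wc.SignalVector(np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            wc.SignalVector(np.array([2.0, 1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            wc.SignalVector(np.array([1.0, 2.0]), np.array([1.0, np.nan]))


class TestCwtRow:
    def test_zero_signal_gives_zero_row(self):
        for name in ("haar", "mexh", "db2"):
            row = wc.cwt_row(np.zeros(32), name, 4)
            np.testing.assert_array_equal(row, np.zeros(32))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, seed, alpha, beta):
        rng = np.random.default_rng(seed)
        f, g = rng.normal(size=(2, 64))
        lhs = wc.cwt_row(alpha * f + beta * g, "mexh", 3)
        rhs = alpha * wc.cwt_row(f, "mexh", 3) + beta * wc.cwt_row(g, "mexh", 3)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    @pytest.mark.parametrize("name,scale", [("mexh", 3), ("db2", 5), ("bior2.4", 2), ("haar", 7)])
    def test_matches_dense_oracle(self, rng, name, scale):
        sig = rng.normal(size=48)
        row = wc.cwt_row(sig, name, scale)
        ref = dense_cwt_row(sig, name, scale)
        np.testing.assert_allclose(row, ref, rtol=0, atol=1e-10 * np.abs(ref).max())

    def test_translation_covariance_interior(self, rng):
        base = np.zeros(80)
        base[25:35] = rng.normal(size=10)
        shifted = np.roll(base, 7)
        a = 4
        r0 = wc.cwt_row(base, "mexh", a)
        r1 = wc.cwt_row(shifted, "mexh", a)
        margin = 4 * a + 10  # keep clear of boundary-affected channels
        np.testing.assert_allclose(r1[margin + 7 : -margin], r0[margin : -margin - 7], atol=1e-10)

    def test_gaussian_peak_coefficient_maximal_at_center(self):
        x = np.arange(128.0)
        sig = np.exp(-0.5 * ((x - 60.0) / 5.0) ** 2)
        row = wc.cwt_row(sig, "mexh", 5)
        assert np.argmax(np.abs(row)) == 60
        assert row[60] > 0  # peak-positive sign convention

    def test_scale_too_large(self):
        with pytest.raises(wc.ScaleTooLargeError):
            wc.cwt_row(np.ones(16), "meyr", 16)

    def test_wide_kernel_warns(self):
        with pytest.warns(UserWarning, match="extension-dominated"):
            wc.cwt_row(np.ones(64), "meyr", 5)


class TestHaarEquivalence:
    """Haar CWT behaves like a first derivative (adjacent moving averages)."""

    def test_equals_difference_of_adjacent_moving_sums(self, rng):
        sig = rng.normal(size=64)
        a = 8
        row = wc.cwt_row(sig, "haar", a)
        ext = wc.boundary_extend(sig, a // 2, "symmetric")
        expected = np.empty(64)
        for b in range(64):
            c = b + a // 2  # position of channel b in the extended signal
            back = ext[c - a // 2 + 1 : c].sum()
            fwd = ext[c + 1 : c + a // 2].sum()
            expected[b] = (back - fwd) / math.sqrt(a)
        np.testing.assert_allclose(row, expected, atol=1e-12)

    def test_zero_at_symmetric_extrema(self):
        x = np.arange(256.0)
        sig = np.exp(-0.5 * ((x - 80) / 9.0) ** 2) - 0.6 * np.exp(-0.5 * ((x - 190) / 11.0) ** 2)
        for a in (5, 9, 16):
            row = wc.cwt_row(sig, "haar", a)
            scale_max = np.abs(row).max()
            assert abs(row[80]) < 1e-10 * scale_max   # peak
            assert abs(row[190]) < 1e-10 * scale_max  # trough

    def test_ramp_rows_constant_sign(self):
        ramp = np.linspace(0.0, 5.0, 64)
        sg = wc.cwt_scalogram(ramp, "haar", [3, 5, 9])
        # increasing signal: backward mean exceeds forward mean nowhere
        assert np.all(sg.coefficients <= 1e-12)


class TestMexhEquivalence:
    def test_proportional_to_second_derivative_of_smoothed_gaussian(self):
        # For f = Gaussian(sigma) the mexh row at scale a is proportional to
        # -(d^2/db^2) of a Gaussian with variance sigma^2 + a^2.
        sigma, a, c = 7.0, 4.0, 100.0
        x = np.arange(200.0)
        sig = np.exp(-0.5 * ((x - c) / sigma) ** 2)
        row = wc.cwt_row(sig, "mexh", a)
        s2 = sigma**2 + a**2
        u = (x - c) ** 2 / s2
        analytic = (1.0 - u) * np.exp(-0.5 * u)  # -g'' shape, peak-positive
        interior = slice(40, 160)
        ratio = row[interior] / analytic[interior]
        keep = np.abs(analytic[interior]) > 0.05
        assert row[int(c)] > 0
        np.testing.assert_allclose(ratio[keep], ratio[keep].mean(), rtol=1e-6)


class TestScalogram:
    def test_single_scale_matches_row(self, rng):
        sig = rng.normal(size=40)
        sg = wc.cwt_scalogram(sig, "sym2", [1])
        np.testing.assert_array_equal(sg.coefficients[0], wc.cwt_row(sig, "sym2", 1))
        assert sg.coefficients.shape == (1, 40)

    def test_rows_match_cwt_row_exactly(self, rng):
        sig = rng.normal(size=40)
        scales = [1, 2, 5, 9]
        sg = wc.cwt_scalogram(sig, "coif1", scales)
        for i, a in enumerate(scales):
            np.testing.assert_array_equal(sg.coefficients[i], wc.cwt_row(sig, "coif1", a))

    def test_scale_validation(self):
        with pytest.raises(ValueError):
            wc.cwt_scalogram(np.ones(16), "mexh", [])
        with pytest.raises(ValueError):
            wc.cwt_scalogram(np.ones(16), "mexh", [3, 2])

    def test_error_annotated_with_scale(self):
        with pytest.raises(wc.ScaleTooLargeError, match="scale 16"):
            wc.cwt_scalogram(np.ones(16), "meyr", [1, 16])
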