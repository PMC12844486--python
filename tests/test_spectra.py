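"""Grid construction, Voigt rendering and normalization."""

import logging

import numpy as np
import pytest

from mrsdenoise import (
    DEFAULT_GRID,
    DEFAULT_VOIGT,
    PeakTable,
    VoigtParams,
    interpolate_to_grid,
    make_grid,
    minmax_normalize,
    peaks_to_spectrum,
    voigt_profile,
)
from mrsdenoise.exceptions import InvalidArgumentError
from mrsdenoise.spectra import Spectrum


class TestMakeGrid:
    def test_canonical_grid(self):
        g = make_grid(1024, 0, 10, 63.885)
        assert g.n_points == 1024
        assert g.spacing == pytest.approx(10 / 1023)
        assert g.axis[0] == 0.0 and g.axis[-1] == 10.0

    def test_two_point_grid_is_exactly_the_endpoints(self):
        g = make_grid(2, 0, 10, 63.885)
        np.testing.assert_array_equal(g.axis, [0.0, 10.0])

    def test_spectral_width(self):
        assert make_grid(11, 0, 10, 100).spectral_width_hz == pytest.approx(1000.0)
        assert DEFAULT_GRID.spectral_width_hz == pytest.approx(638.85)

    @pytest.mark.parametrize(
        "args", [(1, 0, 10, 63.885), (100, 5, 5, 63.885), (100, 5, 3, 63.885),
                 (100, 0, 10, 0.0), (100, 0, 10, -1.0)]
    )
    def test_invalid_arguments(self, args):
        with pytest.raises(InvalidArgumentError):
            make_grid(*args)


class TestVoigtProfile:
    def test_gaussian_limit_peak_value(self):
        sigma = 0.01
        v = voigt_profile(np.array([0.0]), VoigtParams(sigma, 0.0))
        assert v[0] == pytest.approx(1 / (sigma * np.sqrt(2 * np.pi)), rel=1e-12)

    def test_lorentzian_limit_peak_value(self):
        gamma = 0.02
        v = voigt_profile(np.array([0.0]), VoigtParams(0.0, gamma))
        assert v[0] == pytest.approx(1 / (np.pi * gamma), rel=1e-12)

    def test_matches_numerical_convolution_of_gaussian_and_lorentzian(self):
        """Brute-force convolution oracle for the general Voigt case."""
        from scipy.signal import fftconvolve

        sigma, gamma = 0.008, 0.004
        step = 1e-4
        # odd length, exactly symmetric about 0, so "same" centering is exact
        fine = np.linspace(-20.0, 20.0, 400001)
        gauss = np.exp(-fine**2 / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))
        lorentz = gamma / (np.pi * (fine**2 + gamma**2))
        conv = fftconvolve(gauss, lorentz, mode="same") * step
        probe = np.array([0.0, 0.005, -0.01, 0.02, 0.05])
        expected = np.interp(probe, fine, conv)
        got = voigt_profile(probe, VoigtParams(sigma, gamma))
        np.testing.assert_allclose(got, expected, rtol=1e-4)

    def test_unit_area(self):
        x = np.linspace(-5, 5, 200001)
        v = voigt_profile(x, VoigtParams(0.005, 0.005))
        assert np.trapezoid(v, x) == pytest.approx(1.0, rel=0.01)

    def test_symmetry_and_nonnegativity(self):
        x = np.linspace(-1, 1, 999)
        v = voigt_profile(x, VoigtParams(0.01, 0.02))
        assert np.all(v >= 0)
        np.testing.assert_allclose(v, v[::-1], rtol=1e-12)

    def test_both_widths_zero_rejected(self):
        with pytest.raises(InvalidArgumentError):
            VoigtParams(0.0, 0.0)


class TestPeaksToSpectrum:
    def test_cholesterol_argmax_at_main_aliphatic_peak(self, clean_cholesterol):
        ppm_at_max = DEFAULT_GRID.axis[np.argmax(clean_cholesterol.values)]
        assert abs(ppm_at_max - 1.007) <= DEFAULT_GRID.spacing / 2

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidArgumentError):
            peaks_to_spectrum(
                PeakTable(entries=()), DEFAULT_GRID, DEFAULT_VOIGT
            )

    def test_duplicated_peak_doubles_the_spectrum(self):
        one = PeakTable.from_pairs([(5.0, 100.0)])
        two = PeakTable.from_pairs([(5.0, 100.0), (5.0, 100.0)])
        s1 = peaks_to_spectrum(one, DEFAULT_GRID, DEFAULT_VOIGT)
        s2 = peaks_to_spectrum(two, DEFAULT_GRID, DEFAULT_VOIGT)
        np.testing.assert_allclose(s2.values, 2 * s1.values, atol=1e-12)

    def test_linearity_over_merged_tables(self):
        a = PeakTable.from_pairs([(2.0, 300.0), (4.0, 100.0)])
        b = PeakTable.from_pairs([(6.0, 50.0)])
        merged = PeakTable.from_pairs([(2.0, 300.0), (4.0, 100.0), (6.0, 50.0)])
        sa = peaks_to_spectrum(a, DEFAULT_GRID, DEFAULT_VOIGT).values
        sb = peaks_to_spectrum(b, DEFAULT_GRID, DEFAULT_VOIGT).values
        sm = peaks_to_spectrum(merged, DEFAULT_GRID, DEFAULT_VOIGT).values
        np.testing.assert_allclose(sm, sa + sb, atol=1e-10)

    def test_out_of_grid_peak_skipped_with_warning(self, caplog):
        table = PeakTable.from_pairs([(5.0, 100.0), (12.0, 500.0)])
        with caplog.at_level(logging.WARNING):
            s = peaks_to_spectrum(table, DEFAULT_GRID, DEFAULT_VOIGT)
        assert "skipped" in caplog.text
        only_inside = peaks_to_spectrum(
            PeakTable.from_pairs([(5.0, 100.0)]), DEFAULT_GRID, DEFAULT_VOIGT
        )
        np.testing.assert_allclose(s.values, only_inside.values)

    @pytest.mark.parametrize("width", [0.002, 0.005, 0.01, 0.02])
    def test_argmax_stable_across_linewidths(self, bundle, width):
        s = minmax_normalize(
            peaks_to_spectrum(bundle.table, DEFAULT_GRID, VoigtParams(width, width))
        )
        ppm_at_max = DEFAULT_GRID.axis[np.argmax(s.values)]
        assert abs(ppm_at_max - 1.007) <= DEFAULT_GRID.spacing / 2


class TestMinmaxNormalize:
    def test_maps_to_unit_interval(self):
        g = make_grid(3, 0, 10, 63.885)
        s = minmax_normalize(Spectrum(grid=g, values=np.array([2.0, 4.0, 6.0])))
        np.testing.assert_allclose(s.values, [0.0, 0.5, 1.0])
        assert s.normalized

    def test_idempotent(self, clean_cholesterol):
        once = minmax_normalize(clean_cholesterol)
        twice = minmax_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-15)

    def test_constant_spectrum_maps_to_zeros_with_warning(self, caplog):
        g = make_grid(3, 0, 10, 63.885)
        with caplog.at_level(logging.WARNING):
            s = minmax_normalize(Spectrum(grid=g, values=np.full(3, 5.0)))
        np.testing.assert_array_equal(s.values, np.zeros(3))
        assert "degenerate" in caplog.text


class TestInterpolateToGrid:
    def test_identity_on_same_axis(self, clean_cholesterol):
        s = interpolate_to_grid(
            DEFAULT_GRID.axis, clean_cholesterol.values, DEFAULT_GRID
        )
        np.testing.assert_allclose(s.values, clean_cholesterol.values, atol=1e-12)

    def test_linear_ramp_reproduced_on_denser_grid(self):
        coarse = np.linspace(0, 10, 32)
        ramp = 3.0 * coarse + 1.0
        dense = make_grid(1024, 0, 10, 63.885)
        s = interpolate_to_grid(coarse, ramp, dense)
        np.testing.assert_allclose(s.values, 3.0 * dense.axis + 1.0, atol=1e-9)

    def test_zeros_outside_source_range(self):
        src_axis = np.linspace(2, 8, 100)
        s = interpolate_to_grid(src_axis, np.ones(100), DEFAULT_GRID)
        outside = (DEFAULT_GRID.axis < 2) | (DEFAULT_GRID.axis > 8)
        assert np.all(s.values[outside] == 0)
        inside = (DEFAULT_GRID.axis >= 2) & (DEFAULT_GRID.axis <= 8)
        np.testing.assert_allclose(s.values[inside], 1.0)

    def test_descending_axis_canonicalized(self):
        axis = np.linspace(10, 0, 64)
        vals = axis**2
        s = interpolate_to_grid(axis, vals, make_grid(64, 0, 10, 63.885))
        np.testing.assert_allclose(s.values, s.grid.axis**2, atol=1e-9)

    def test_non_monotone_axis_rejected(self):
        axis = np.array([0.0, 1.0, 1.0, 2.0])
        with pytest.raises(InvalidArgumentError):
            interpolate_to_grid(axis, np.zeros(4), DEFAULT_GRID)
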