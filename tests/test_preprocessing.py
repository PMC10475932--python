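"""Scatter correction and derivative math: closed forms and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nirscal as nc
from nirscal.preprocessing import trim_per_side

from conftest import random_spectra


def make_set(rows, step=0.5):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    wl = 400.0 + step * np.arange(rows.shape[1])
    return nc.SpectraSet([f"s{i}" for i in range(rows.shape[0])], wl, rows)


class TestSNV:
    def test_three_point_row(self):
        out = nc.snv(make_set([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.absorbance, [[-1.0, 0.0, 1.0]])

    def test_rows_standardized(self, rng):
        out = nc.snv(random_spectra(rng, n=5, p=4201))
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1,
                                   rtol=0, atol=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(0.01, 100), b=st.floats(-50, 50), seed=st.integers(0, 10))
    def test_affine_invariance(self, a, b, seed):
        base = np.random.default_rng(seed).normal(size=(1, 120))
        ref = nc.snv(make_set(base)).absorbance
        scaled = nc.snv(make_set(a * base + b)).absorbance
        np.testing.assert_allclose(scaled, ref, atol=1e-8)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="s0"):
            nc.snv(make_set([[2.0] * 10]))


class TestDetrend:
    def test_annihilates_own_degree(self, rng):
        wl = 400.0 + 0.5 * np.arange(300)
        quad = 2.0 + 0.003 * wl - 1e-6 * wl**2
        out = nc.detrend(make_set(quad[None, :]), degree=2)
        np.testing.assert_allclose(out.absorbance, 0, atol=1e-8)

    def test_linear_ramp_degree_one(self):
        ramp = np.linspace(0, 1, 50)
        out = nc.detrend(make_set(ramp[None, :]), degree=1)
        np.testing.assert_allclose(out.absorbance, 0, atol=1e-10)

    def test_residual_orthogonal_to_basis(self, rng):
        spectra = random_spectra(rng, n=4, p=500)
        out = nc.detrend(spectra, degree=2)
        wl = spectra.wavelengths
        u = (wl - wl.mean()) / np.ptp(wl)
        basis = np.vander(u, 3)
        # refitting the polynomial to the residual gives ~zero coefficients
        coef, *_ = np.linalg.lstsq(basis, out.absorbance.T, rcond=None)
        scale = np.abs(spectra.absorbance).max()
        assert np.abs(coef).max() < 1e-8 * scale

    def test_band_on_quadratic_baseline(self):
        wl = 400.0 + 0.5 * np.arange(1000)
        u = (wl - wl.mean()) / 100.0
        baseline = 0.5 + 0.1 * u + 0.02 * u**2
        band = 0.3 * np.exp(-0.5 * ((wl - 600.0) / 20.0) ** 2)
        detrended_band = nc.detrend(make_set(band[None, :]), 2).absorbance
        detrended_sum = nc.detrend(make_set((baseline + band)[None, :]), 2).absorbance
        np.testing.assert_allclose(detrended_sum, detrended_band, atol=1e-8)

    def test_degree_too_large(self):
        with pytest.raises(ValueError):
            nc.detrend(make_set([[1.0, 2.0, 3.0]]), degree=5)


class TestGapSegmentDerivative:
    def test_constant_spectrum_gives_zeros(self):
        out = nc.gap_segment_derivative(
            make_set([[5.0] * 100]), nc.MathTreatment(2, 8.0, 6, 1))
        np.testing.assert_allclose(out.absorbance, 0, atol=1e-12)

    @pytest.mark.parametrize("gap_points", [2, 4, 8, 16])
    def test_second_difference_of_square_is_2G2(self, gap_points):
        # unit-index grid (step 1 nm, gap G nm = G points)
        n = 120
        wl = np.arange(n, dtype=float)
        f = wl**2
        sp = nc.SpectraSet(["x"], wl, f[None, :])
        out = nc.gap_segment_derivative(
            sp, nc.MathTreatment(2, float(gap_points), 1, 1))
        np.testing.assert_allclose(out.absorbance, 2.0 * gap_points**2)

    def test_identity_treatment(self, rng):
        sp = random_spectra(rng)
        out = nc.gap_segment_derivative(sp, nc.MathTreatment(0, 0.0, 1, 1))
        np.testing.assert_array_equal(out.absorbance, sp.absorbance)
        np.testing.assert_array_equal(out.wavelengths, sp.wavelengths)

    def test_linearity(self, rng):
        t = nc.MathTreatment(2, 8.0, 6, 1)
        x = random_spectra(rng, n=1, p=300)
        y = random_spectra(rng, n=1, p=300)
        combo = nc.SpectraSet(["c"], x.wavelengths,
                              2.5 * x.absorbance - 1.5 * y.absorbance)
        lhs = nc.gap_segment_derivative(combo, t).absorbance
        rhs = (2.5 * nc.gap_segment_derivative(x, t).absorbance
               - 1.5 * nc.gap_segment_derivative(y, t).absorbance)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_gap_must_fit_grid(self):
        with pytest.raises(ValueError):
            nc.gap_segment_derivative(
                make_set([[1.0] * 10]), nc.MathTreatment(2, 8.0, 1, 1))

    def test_odd_gap_points_rejected(self):
        # 1.5 nm gap on a 0.5 nm grid = 3 points: no integral half-gap
        with pytest.raises(ValueError, match="even"):
            nc.gap_segment_derivative(
                make_set([[1.0] * 50]), nc.MathTreatment(1, 1.5, 1, 1))


class TestMathTreatmentParsing:
    def test_default_second_derivative_code(self):
        t = nc.parse_math_treatment("2,8,6,1")
        assert (t.derivative_order, t.gap_nm, t.smooth_points,
                t.second_smooth_points) == (2, 8.0, 6, 1)

    def test_identity_code(self):
        t = nc.parse_math_treatment("0,0,1,1")
        assert t.derivative_order == 0 and t.smooth_points == 1

    @pytest.mark.parametrize("bad", ["2,8,6", "2,8,6,1,0", "a,b,c,d", ""])
    def test_malformed_codes(self, bad):
        with pytest.raises(ValueError):
            nc.parse_math_treatment(bad)

    def test_roundtrip_code(self):
        assert nc.parse_math_treatment("2,8,6,1").code() == "2,8,6,1"


class TestPipeline:
    def test_noop_settings_return_input(self, rng):
        sp = random_spectra(rng)
        settings = nc.PreprocessingSettings(
            scatter_mode="none", treatment=nc.MathTreatment(0, 0.0, 1, 1))
        out = nc.apply_pipeline(sp, settings)
        np.testing.assert_array_equal(out.absorbance, sp.absorbance)

    def test_multiplicative_scatter_removed_by_snv(self, rng):
        clean = np.abs(rng.normal(size=500)) + 0.5
        settings = nc.PreprocessingSettings(
            scatter_mode="snv", treatment=nc.MathTreatment(0, 0.0, 1, 1))
        outs = [nc.apply_pipeline(make_set((a * clean)[None, :]), settings).absorbance
                for a in (0.5, 2.0)]
        np.testing.assert_allclose(outs[0], outs[1], atol=1e-8)

    def test_default_settings_trim_documented(self, rng):
        sp = random_spectra(rng, n=2, p=4201)
        out = nc.apply_pipeline(sp, nc.PreprocessingSettings())
        left, right = trim_per_side(nc.PreprocessingSettings(), 0.5)
        # smooth 6 -> 3+2; two gap passes of 8 nm (16 pts, half 8) -> 16+16
        assert (left, right) == (19, 18)
        assert out.n_wavelengths == 4201 - left - right

    def test_pipeline_deterministic(self, rng):
        sp = random_spectra(rng, n=3, p=600)
        a = nc.apply_pipeline(sp, nc.PreprocessingSettings())
        b = nc.apply_pipeline(sp, nc.PreprocessingSettings())
        np.testing.assert_array_equal(a.absorbance, b.absorbance)
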