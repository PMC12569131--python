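"""Thin-film wing model: fringe function, resonances, thickness fitting."""

import numpy as np
import pytest

from mosqnir import (
    ChitinDispersion,
    band_ratio,
    brdf_cos_power,
    fit_wing,
    fringe_reflectance,
    fresnel_reflectance,
    modulation_depth,
    n_chitin,
    resonant_wavelengths,
    wing_model,
)
from mosqnir.spectra import Spectrum
from mosqnir.wing import WingFit
from mosqnir import simulate as sim


class TestFringeFunction:
    def test_zero_thickness_gives_zero(self, wing_grid):
        np.testing.assert_array_equal(fringe_reflectance(wing_grid, 0.0), 0.0)

    def test_fringe_minimum_at_full_wave_phase(self):
        # lambda solving 2 pi d n / lambda = pi  ->  lambda = 2 d n(lambda)
        d = 300.0
        lam = 2 * d * 1.517
        for _ in range(100):
            lam = 2 * d * n_chitin(lam)
        assert fringe_reflectance(lam, d) == pytest.approx(0.0, abs=1e-20)

    def test_peak_value_is_fresnel_bound(self):
        # at the m=1 resonance sin^2 = 1 exactly, so F = 4R/(1+R)^2
        d = 174.0
        lam = resonant_wavelengths(d)[0]
        R = fresnel_reflectance(1.0, n_chitin(lam))
        assert fringe_reflectance(lam, d) == pytest.approx(4 * R / (1 + R) ** 2, rel=1e-12)

    def test_bounded_by_fresnel_envelope(self, wing_grid):
        F = fringe_reflectance(wing_grid, 225.0)
        R = fresnel_reflectance(1.0, n_chitin(wing_grid))
        assert np.all(F >= 0)
        assert np.all(F <= 4 * R / (1 + R) ** 2 + 1e-15)

    def test_exact_scale_invariance_without_dispersion(self):
        # with the dispersion coefficient frozen at zero, (d, lam) -> (c d, c lam)
        # leaves the fringe unchanged
        disp = ChitinDispersion(dispersion_coeff_nm2=0.0)
        lam = np.linspace(900.0, 2500.0, 97)
        c = 1.7
        np.testing.assert_allclose(
            fringe_reflectance(lam, 200.0, disp),
            fringe_reflectance(c * lam, c * 200.0, disp),
            rtol=1e-12,
        )


class TestResonantWavelengths:
    def test_normal_incidence_m1_fixed_point(self):
        d = 174.0
        lam = resonant_wavelengths(d, theta_deg=0.0, m_max=1)[0]
        assert lam == pytest.approx(4 * d * n_chitin(lam), abs=1e-5)

    def test_modes_strictly_decreasing(self):
        lams = resonant_wavelengths(400.0, m_max=4)
        assert np.all(np.diff(lams) < 0)

    def test_oblique_incidence_shifts_blue(self):
        assert resonant_wavelengths(250.0, 30.0)[0] < resonant_wavelengths(250.0, 0.0)[0]

    def test_matches_bruteforce_phase_argmax(self):
        # independent oracle: argmax of the fringe with the Fresnel factor
        # frozen (the resonance condition), scanned at 0.01 nm
        for d in (120.0, 174.0, 260.0, 410.0):
            lam_cf = resonant_wavelengths(d)[0]
            grid = np.arange(0.8 * lam_cf, 1.2 * lam_cf, 0.01)
            R0 = fresnel_reflectance(1.0, n_chitin(lam_cf))
            s = np.sin(2 * np.pi * d * n_chitin(grid) / grid) ** 2
            F = 4 * R0 * s / ((1 - R0) ** 2 + 4 * R0 * s)
            assert abs(grid[np.argmax(F)] - lam_cf) < 0.1

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            resonant_wavelengths(-1.0)
        with pytest.raises(ValueError):
            resonant_wavelengths(200.0, theta_deg=95.0)
        with pytest.raises(ValueError):
            resonant_wavelengths(200.0, m_max=0)


class TestWingModel:
    def test_no_fringe_term_gives_flat_half_bias(self, wing_grid):
        np.testing.assert_allclose(wing_model(wing_grid, 200.0, 0.0, 0.4), 0.2)

    def test_zero_bias_is_scaled_fringe(self, wing_grid):
        np.testing.assert_allclose(
            wing_model(wing_grid, 200.0, 0.8, 0.0),
            0.4 * fringe_reflectance(wing_grid, 200.0),
        )

    def test_value_at_resonance_composes_with_fringe_peak(self):
        d, a, b = 220.0, 0.9, 0.1
        lam = resonant_wavelengths(d)[0]
        Fmax = fringe_reflectance(lam, d)
        assert wing_model(lam, d, a, b) == pytest.approx((a * Fmax + b) / 2, rel=1e-12)

    def test_general_k_requires_lambda0(self, wing_grid):
        with pytest.raises(ValueError):
            wing_model(wing_grid, 200.0, 0.9, 0.1, k=2.0)


class TestFitWing:
    def test_noiseless_self_consistency(self, noiseless_wing):
        fit = fit_wing(noiseless_wing)
        assert fit.d_nm == pytest.approx(250.0, abs=1e-3)
        assert fit.a == pytest.approx(0.9, abs=1e-6)
        assert fit.b == pytest.approx(0.1, abs=1e-6)
        assert fit.r2_adj > 0.999999

    @pytest.mark.parametrize("d_true", [160.0, 250.0, 340.0])
    def test_noiseless_matches_grid_search_oracle(self, d_true, wing_grid):
        spec = sim.gen_wing_spectrum(d_true, snr=1e12, seed=3)
        fit = fit_wing(spec)
        # independent oracle: SSE over a fine thickness grid with the
        # amplitude/bias profiled out linearly
        ones = np.ones_like(wing_grid)
        best = (np.inf, None)
        for d in np.arange(d_true - 20.0, d_true + 20.0, 0.01):
            X = np.column_stack([fringe_reflectance(wing_grid, d), ones])
            c, *_ = np.linalg.lstsq(X, spec.reflectance, rcond=None)
            sse = float(np.sum((X @ c - spec.reflectance) ** 2))
            if sse < best[0]:
                best = (sse, d)
        assert fit.d_nm == pytest.approx(best[1], abs=0.01)

    def test_modulation_depth_round_trip(self):
        # spectra generated at depth 0.92 (a=0.92, b=0.08) recover the depth
        depths = []
        for i in range(20):
            spec = sim.gen_wing_spectrum(220.0, a=0.92, b=0.08, seed=[7, i])
            depths.append(fit_wing(spec).modulation_depth)
        assert np.median(depths) == pytest.approx(0.92, abs=0.01)

    def test_depth_invariant_to_overall_scaling(self):
        spec = sim.gen_wing_spectrum(200.0, seed=11)
        scaled = Spectrum(spec.wavelengths_nm, 1.3 * spec.reflectance)
        f1, f2 = fit_wing(spec), fit_wing(scaled)
        assert f1.modulation_depth == pytest.approx(f2.modulation_depth, abs=1e-3)
        assert f1.d_nm == pytest.approx(f2.d_nm, abs=0.05)

    def test_too_few_bands_rejected(self):
        lam = np.linspace(900, 2500, 40)
        with pytest.raises(ValueError):
            fit_wing(sim.gen_wing_spectrum(200.0, lambda_grid=lam, seed=0))

    def test_out_of_range_reflectance_rejected(self, wing_grid):
        with pytest.raises(ValueError):
            fit_wing(Spectrum(wing_grid, np.full(wing_grid.size, 2.0)))


class TestModulationDepth:
    def test_equal_coefficients_give_half(self):
        fit = WingFit(200, 0.3, 0.3, 0, 1, 0, 0, 0.99, 0.5, 288, True, False)
        assert modulation_depth(fit) == 0.5

    def test_zero_bias_gives_unity(self):
        fit = WingFit(200, 0.7, 0.0, 0, 1, 0, 0, 0.99, 1.0, 288, True, False)
        assert modulation_depth(fit) == 1.0

    def test_degenerate_coefficients_raise(self):
        fit = WingFit(200, 0.0, 0.0, 0, 1, 0, 0, 0.99, np.nan, 288, True, False)
        with pytest.raises(ValueError):
            modulation_depth(fit)


class TestBandRatio:
    def test_identical_bands_ratio_one(self):
        assert band_ratio(230.0, 980.0, 980.0) == 1.0

    def test_degenerate_film_guarded(self):
        with pytest.raises(ZeroDivisionError):
            band_ratio(0.0, 808.0, 980.0)

    def test_ratio_crosses_unity_across_thickness_span(self):
        d = np.arange(150.0, 350.0, 1.0)
        ratios = np.array([band_ratio(di, 808.0, 980.0) for di in d])
        assert np.any(ratios > 1) and np.any(ratios < 1)


class TestDirectionalScattering:
    def test_normal_incidence_is_unity(self):
        for r in (0.05, 0.5, 1.0):
            assert brdf_cos_power(0.0, r) == 1.0

    def test_ideal_diffuser_is_cosine(self):
        th = np.linspace(0, 90, 10)
        np.testing.assert_allclose(brdf_cos_power(th, 1.0), np.cos(np.deg2rad(th)))

    def test_rough_mirror_sharp_lobe(self):
        assert brdf_cos_power(25.8, 0.1) == pytest.approx(
            np.cos(np.deg2rad(25.8)) ** 10, rel=1e-12
        )

    def test_domain_errors(self):
        for bad_r in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                brdf_cos_power(10.0, bad_r)
        with pytest.raises(ValueError):
            brdf_cos_power(100.0, 0.5)
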