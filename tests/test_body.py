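"""Body reflectance: specular/diffuse split, pathlength fitting, spots."""

import numpy as np
import pytest

from mosqnir import (
    DEFAULT_CONSTANTS,
    PolarizedSpectra,
    absorbance,
    body_forward,
    fit_body,
    fit_spot,
    mu_water,
    scatterance,
    specular_estimate,
    spot_forward,
)
from mosqnir import simulate as sim


class TestSpecularEstimate:
    def test_identical_channels_give_zero(self, body_grid):
        r = np.full(body_grid.size, 0.2)
        assert specular_estimate(PolarizedSpectra(body_grid, r, r)) == 0.0

    def test_constant_offset_recovered_exactly(self, body_grid):
        r = np.linspace(0.1, 0.3, body_grid.size)
        pair = PolarizedSpectra(body_grid, r + 0.03, r)
        assert specular_estimate(pair) == pytest.approx(0.03, abs=1e-15)

    def test_invariant_to_common_additive_spectrum(self, body_grid):
        rng = np.random.default_rng(0)
        base = 0.2 + 0.05 * rng.random(body_grid.size)
        extra = 0.1 * rng.random(body_grid.size)
        p1 = PolarizedSpectra(body_grid, base + 0.04, base)
        p2 = PolarizedSpectra(body_grid, base + extra + 0.04, base + extra)
        assert specular_estimate(p1) == pytest.approx(specular_estimate(p2), abs=1e-12)

    def test_noiseless_generator_inverse(self):
        pair = sim.gen_body_spectra(r_spec=0.03, snr_copol=1e15, snr_depol=1e15, seed=0)
        assert specular_estimate(pair) == pytest.approx(0.03, abs=1e-9)


class TestForwardModels:
    def test_scatterance_unity_at_half_wavelength(self):
        for alpha in (0.5, 1.0, 4.2):
            assert scatterance(1215.0, 1215.0, alpha) == 1.0

    def test_scatterance_flat_for_zero_exponent(self, body_grid):
        np.testing.assert_array_equal(scatterance(body_grid, 500.0, 0.0), 1.0)

    def test_scatterance_octave_value(self):
        assert scatterance(2430.0, 1215.0, 4.2) == pytest.approx(2.0**-4.2, rel=1e-12)

    def test_absorbance_zero_pathlengths(self, body_grid):
        np.testing.assert_array_equal(absorbance(body_grid, 0.0, 0.0), 0.0)

    def test_absorbance_pure_water_peaks_near_1450(self, body_grid):
        A = absorbance(body_grid, 51.0, 0.0)
        assert abs(body_grid[np.argmax(A)] - 1450.0) < 30.0
        assert absorbance(1450.0, 51.0, 0.0) == pytest.approx(51.0 * mu_water(1450.0))

    def test_body_forward_half_reflectance_point(self):
        # no absorption, lambda = D_half: S = 1, diffuse term = 1/2
        assert body_forward(1215.0, 0.04, 1215.0, 3.0, 0.0, 0.0) == pytest.approx(0.54)

    def test_body_forward_limits(self):
        # S -> infinity: diffuse term -> 1
        assert body_forward(1000.0, 0.02, 4999.0, 10.0, 0.0, 0.0) == pytest.approx(
            1.02, abs=1e-3
        )
        # S -> 0 (steep cut, lambda >> D_half): only the specular term survives
        assert body_forward(1600.0, 0.02, 200.0, 10.0, 0.0, 0.0) == pytest.approx(
            0.02, abs=1e-6
        )

    def test_body_forward_bounded(self, body_grid):
        r = body_forward(body_grid, 0.03, 330.0, 1.0, 51.0, 25.0)
        assert np.all(r >= 0.03) and np.all(r < 1.03)

    def test_monotone_decreasing_in_each_pathlength(self):
        lam = 1450.0
        base = body_forward(lam, 0.0, 330.0, 1.0, 51.0, 25.0)
        assert body_forward(lam, 0.0, 330.0, 1.0, 52.0, 25.0) < base
        assert body_forward(lam, 0.0, 330.0, 1.0, 51.0, 26.0) < base


class TestFitBody:
    def test_noiseless_exact_recovery(self, noiseless_body):
        co, de = fit_body(noiseless_body)
        assert co.d_half_nm == pytest.approx(330.0, rel=1e-4)
        assert co.alpha == pytest.approx(1.0, rel=1e-4)
        assert co.ell_h2o_um == pytest.approx(51.0, rel=1e-3)
        assert co.ell_mel_um == pytest.approx(25.0, rel=1e-3)
        assert de.ell_h2o_um == pytest.approx(51.0, rel=1e-3)
        assert co.polarization == "co" and de.polarization == "de"

    def test_noiseless_beats_coarse_grid_oracle(self, noiseless_body, body_grid):
        # independent oracle: SSE argmin over a 10-steps-per-axis grid must
        # be no better than the fitted optimum, and the fit must sit in the
        # basin the grid identifies
        co, _ = fit_body(noiseless_body)
        y = noiseless_body.r_copol - specular_estimate(noiseless_body)
        muw = DEFAULT_CONSTANTS.water(body_grid)
        mum = DEFAULT_CONSTANTS.melanin(body_grid)

        def sse(dh, al, lw, lm):
            S = (dh / body_grid) ** al
            return float(np.sum((S / (1 + S + lw * muw + lm * mum) - y) ** 2))

        grid_best, grid_arg = np.inf, None
        for dh in np.linspace(150, 1000, 10):
            for al in np.linspace(0.2, 3.0, 10):
                for lw in np.linspace(5, 150, 10):
                    for lm in np.linspace(5, 100, 10):
                        v = sse(dh, al, lw, lm)
                        if v < grid_best:
                            grid_best, grid_arg = v, (dh, al, lw, lm)
        fit_sse = sse(co.d_half_nm, co.alpha, co.ell_h2o_um, co.ell_mel_um)
        assert fit_sse <= grid_best + 1e-12
        # the coarse argmin lands in the neighbourhood of the truth
        assert abs(grid_arg[2] - 51.0) < 20.0 and abs(grid_arg[3] - 25.0) < 15.0

    def test_depolarized_channel_fitted_without_subtraction(self):
        pair = sim.gen_body_spectra(
            depol_params={"ell_h2o_um": 61.0, "ell_mel_um": 32.0},
            snr_copol=1e12,
            snr_depol=1e12,
            seed=0,
        )
        _, de = fit_body(pair)
        assert de.ell_h2o_um == pytest.approx(61.0, rel=1e-3)
        assert de.ell_mel_um == pytest.approx(32.0, rel=1e-3)

    def test_wavelengths_above_cut_excluded(self):
        lam = np.linspace(900.0, 2400.0, 500)
        pair = sim.gen_body_spectra(lambda_grid=lam, snr_copol=1e12, snr_depol=1e12, seed=0)
        co, _ = fit_body(pair, lambda_max_nm=1600.0)
        assert co.n_bands == int(np.sum(lam <= 1600.0))

    def test_insufficient_coverage_rejected(self):
        lam = np.linspace(900.0, 1200.0, 150)
        pair = sim.gen_body_spectra(lambda_grid=lam, seed=0)
        with pytest.raises(ValueError):
            fit_body(pair)

    def test_melanin_free_data_flags_indeterminate(self):
        flagged = 0
        for i in range(20):
            pair = sim.gen_body_spectra(ell_mel_um=0.0, seed=[21, i])
            co, _ = fit_body(pair)
            flagged += "ell_mel_um" in co.indeterminate_params
        assert flagged >= 16  # >= 80 %


class TestSpotModel:
    def test_half_reflectance_at_cut(self):
        for alpha in (1.0, 4.2, 8.0):
            assert spot_forward(1215.0, 1215.0, alpha) == 0.5

    def test_flat_for_zero_steepness(self, body_grid):
        np.testing.assert_array_equal(spot_forward(body_grid, 1215.0, 0.0), 0.5)

    def test_shortpass_decreasing(self, body_grid):
        assert np.all(np.diff(spot_forward(body_grid, 1215.0, 4.2)) < 0)

    def test_direct_evaluation(self):
        assert spot_forward(900.0, 1215.0, 4.2) == pytest.approx(
            1.0 / (1.0 + (900.0 / 1215.0) ** 4.2), rel=1e-12
        )

    def test_noiseless_fit_matches_grid_oracle(self, body_grid):
        spec = sim.gen_spot_spectrum(1215.0, 4.2, snr=1e12, seed=0)
        fit = fit_spot(spec)
        assert fit.d_half_nm == pytest.approx(1215.0, abs=0.01)
        assert fit.alpha == pytest.approx(4.2, abs=1e-4)
        # 2-d grid argmin oracle around the optimum
        best = (np.inf, None)
        for dh in np.arange(1195.0, 1235.0, 0.5):
            for al in np.arange(3.8, 4.6, 0.01):
                sse = float(np.sum((spot_forward(body_grid, dh, al) - spec.reflectance) ** 2))
                if sse < best[0]:
                    best = (sse, (dh, al))
        assert fit.d_half_nm == pytest.approx(best[1][0], abs=0.5)
        assert fit.alpha == pytest.approx(best[1][1], abs=0.01)


class TestValidation:
    def test_mismatched_grids_rejected(self, body_grid):
        with pytest.raises(ValueError):
            PolarizedSpectra(body_grid, np.zeros(body_grid.size), np.zeros(10))

    def test_strongly_negative_reflectance_rejected(self, body_grid):
        bad = np.full(body_grid.size, -0.2)
        with pytest.raises(ValueError):
            PolarizedSpectra(body_grid, bad, bad)
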