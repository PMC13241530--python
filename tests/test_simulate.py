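"""Synthetic spectra generator: Beer-Lambert structure, noise, plasma effects."""

import numpy as np
import pytest

import chemocal as cc
from chemocal.datasets import ConfigurationError, ValidationError

ANALYTES = ["CFPM", "TAZO"]


class TestPureSpectra:
    def test_default_grid_has_141_points(self, pure):
        for p in pure.values():
            assert p.epsilon.shape == (141,)

    def test_single_band_peaks_at_its_center(self, grid):
        spectra1 = cc.build_pure_spectra({"X": [cc.GaussianBand(250.0, 5.0, 0.3)]}, grid)
        wl = grid.points
        assert spectra1["X"].epsilon[wl == 250.0] == pytest.approx(0.3)

    def test_gaussian_band_hand_value(self, grid):
        # band (211, sigma 8, peak 0.12) evaluated 16 nm off-center
        spectra1 = cc.build_pure_spectra({"X": [cc.GaussianBand(211.0, 8.0, 0.12)]}, grid)
        expected = 0.12 * np.exp(-(16.0**2) / (2 * 8.0**2))
        got = spectra1["X"].epsilon[grid.points == 227.0][0]
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.0162, abs=5e-5)

    def test_empty_band_list_rejected(self, grid):
        with pytest.raises(ConfigurationError):
            cc.build_pure_spectra({"X": []}, grid)
        with pytest.raises(ConfigurationError):
            cc.build_pure_spectra({}, grid)

    def test_severe_overlap_below_250nm(self, pure, grid):
        wl = grid.points
        m = (wl >= 210) & (wl <= 250)
        a = pure["CFPM"].epsilon[m]
        b = pure["TAZO"].epsilon[m]
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos > 0.7

    def test_no_interference_free_wavelength(self, pure):
        # both analytes absorb (strictly positively) everywhere in the window
        for p in pure.values():
            assert np.all(p.epsilon > 0)


class TestMixtures:
    def test_zero_concentration_zero_noise_gives_zero_matrix(self, pure):
        conc = cc.ConcentrationTable(ANALYTES, np.zeros((3, 2)))
        X = cc.simulate_mixtures(pure, conc, cc.NoiseModel(0.0))
        assert np.all(X.values == 0)

    def test_beer_lambert_matrix_product_oracle(self, pure):
        conc = cc.ConcentrationTable(ANALYTES, np.array([[5.0, 10.0]]))
        X = cc.simulate_mixtures(pure, conc, cc.NoiseModel(0.0))
        expected = 5.0 * pure["CFPM"].epsilon + 10.0 * pure["TAZO"].epsilon
        np.testing.assert_allclose(X.values[0], expected, rtol=0, atol=1e-12)

    def test_additivity_and_linearity(self, pure):
        rng = np.random.default_rng(3)
        c = rng.uniform(1, 9, size=(4, 2))
        single = cc.ConcentrationTable(ANALYTES, c)
        double = cc.ConcentrationTable(ANALYTES, 2 * c)
        X1 = cc.simulate_mixtures(pure, single, cc.NoiseModel(0.0))
        X2 = cc.simulate_mixtures(pure, double, cc.NoiseModel(0.0))
        np.testing.assert_allclose(X2.values, 2 * X1.values, atol=1e-12)
        # mixture equals the sum of per-analyte contributions
        only_a = cc.ConcentrationTable(ANALYTES, np.column_stack([c[:, 0], 0 * c[:, 1]]))
        only_b = cc.ConcentrationTable(ANALYTES, np.column_stack([0 * c[:, 0], c[:, 1]]))
        Xa = cc.simulate_mixtures(pure, only_a, cc.NoiseModel(0.0))
        Xb = cc.simulate_mixtures(pure, only_b, cc.NoiseModel(0.0))
        np.testing.assert_allclose(X1.values, Xa.values + Xb.values, atol=1e-12)

    def test_negative_concentration_rejected(self, pure):
        conc = cc.ConcentrationTable(ANALYTES, np.array([[1.0, -0.5]]))
        with pytest.raises(ValidationError):
            cc.simulate_mixtures(pure, conc, cc.NoiseModel(0.0))

    def test_seed_determinism(self, pure, y_cal):
        a = cc.simulate_mixtures(pure, y_cal, cc.NoiseModel(0.002, 0.001, seed=5))
        b = cc.simulate_mixtures(pure, y_cal, cc.NoiseModel(0.002, 0.001, seed=5))
        assert np.array_equal(a.values, b.values)
        c = cc.simulate_mixtures(pure, y_cal, cc.NoiseModel(0.002, 0.001, seed=6))
        assert not np.array_equal(a.values, c.values)

    def test_noise_sd_calibration(self, pure):
        # >= 1e4 cells: 100 samples x 141 wavelengths
        rng = np.random.default_rng(0)
        conc = cc.ConcentrationTable(ANALYTES, rng.uniform(1, 9, size=(100, 2)))
        clean = cc.simulate_mixtures(pure, conc, cc.NoiseModel(0.0))
        noisy = cc.simulate_mixtures(pure, conc, cc.NoiseModel(0.002, seed=21))
        resid = noisy.values - clean.values
        assert resid.size >= 10_000
        assert resid.std() == pytest.approx(0.002, rel=0.05)


class TestPlasma:
    def test_no_suppression_no_background_matches_neat(self, pure, y_cal):
        mx = cc.MatrixEffectSpec({}, background_amplitude=0.0)
        Xp, mf = cc.simulate_plasma_set(pure, y_cal, cc.NoiseModel(0.0), mx)
        Xn = cc.simulate_mixtures(pure, y_cal, cc.NoiseModel(0.0))
        np.testing.assert_allclose(Xp.values, Xn.values, atol=1e-12)
        assert mf == {"CFPM": 1.0, "TAZO": 1.0}

    def test_true_matrix_factor_from_suppression(self, pure, y_cal):
        mx = cc.MatrixEffectSpec({"TAZO": 0.0235}, background_amplitude=0.0)
        _, mf = cc.simulate_plasma_set(pure, y_cal, cc.NoiseModel(0.0), mx)
        assert mf["TAZO"] == pytest.approx(0.9765)

    def test_suppression_at_or_above_one_rejected(self):
        with pytest.raises(ValidationError):
            cc.MatrixEffectSpec({"CFPM": 1.0})

    def test_model_sees_the_suppression_ratio(self, grid):
        """A model trained on neat standards predicts suppressed concentrations."""
        pure1 = cc.build_pure_spectra({"CFPM": cc.DEFAULT_BAND_LIBRARY["CFPM"]}, grid)
        Y = cc.ConcentrationTable(["CFPM"], np.arange(2.0, 18.0, 3.0)[:, None])
        X = cc.simulate_mixtures(pure1, Y, cc.NoiseModel(0.0))
        model = cc.fit_pcr(X, Y)
        mx = cc.MatrixEffectSpec({"CFPM": 0.05}, background_amplitude=0.0)
        Xp, _ = cc.simulate_plasma_set(pure1, Y, cc.NoiseModel(0.0), mx)
        ratio = model.predict(Xp).values / Y.values
        np.testing.assert_allclose(ratio, 0.95, atol=1e-8)
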