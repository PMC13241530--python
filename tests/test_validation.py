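"""Validation metrics, NAS figures of merit, t/ANOVA/EJCR and matrix factors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import chemocal as cc
from chemocal.datasets import ValidationError


def pset(y, yhat):
    return cc.PredictionSet(np.asarray(y, float), np.asarray(yhat, float))


class TestMetrics:
    def test_perfect_prediction_is_all_zero(self):
        m = cc.compute_metrics(pset([1, 2, 3], [1, 2, 3]))
        assert m.rmse == m.bias == m.sec == 0.0
        assert m.mean_recovery == pytest.approx(100.0)

    def test_constant_offset_is_pure_bias(self):
        m = cc.compute_metrics(pset([1, 2, 3], [2, 3, 4]))
        assert m.rmse == pytest.approx(1.0)
        assert m.bias == pytest.approx(-1.0)
        assert m.sec == pytest.approx(0.0)
        assert m.bcrmsep == pytest.approx(0.0)

    def test_single_point_error_hand_values(self):
        m = cc.compute_metrics(pset([1, 2, 3], [1, 2, 4]))
        assert m.rmse == pytest.approx(np.sqrt(1 / 3))
        assert m.bias == pytest.approx(-1 / 3)
        sec = np.sqrt(((1 / 3) ** 2 + (1 / 3) ** 2 + (2 / 3) ** 2) / 2)
        assert m.sec == pytest.approx(sec)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rmse_decomposition_identity(self, seed):
        """RMSE^2 = bias^2 + (n-1)/n * SEC^2 on arbitrary prediction sets."""
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 30)
        y = rng.uniform(1, 20, n)
        yhat = y + rng.normal(0, 1, n)
        m = cc.compute_metrics(pset(y, yhat))
        assert m.rmse**2 == pytest.approx(
            m.bias**2 + (n - 1) / n * m.sec**2, abs=1e-9
        )
        assert m.rmse >= abs(m.bias) - 1e-12
        # the typeset variant differs from the standard form by sqrt(n) exactly
        assert m.rrmsep_over_n == pytest.approx(m.rrmsep / np.sqrt(n), rel=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            cc.compute_metrics(pset([1.0], [1.0]))


class TestNas:
    def test_orthogonal_spectra_keep_full_signal(self):
        S = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        f = cc.nas_figures_of_merit(S, 0, noise_sd=0.01)
        np.testing.assert_allclose(f.nas_vector, S[:, 0], atol=1e-12)
        assert f.sensitivity == pytest.approx(1.0)

    def test_zero_noise_means_zero_limits(self):
        S = np.array([[1.0, 0.5], [0.2, 1.0], [0.1, 0.3]])
        f = cc.nas_figures_of_merit(S, 0, noise_sd=0.0)
        assert f.lod == f.loq == 0.0

    def test_loq_lod_convention(self):
        S = np.array([[1.0, 0.5], [0.2, 1.0], [0.1, 0.3]])
        f = cc.nas_figures_of_merit(S, 1, noise_sd=0.004)
        assert f.loq / f.lod == pytest.approx(10 / 3.3)
        # the convention maps an LOD of 0.0396 ug/mL to an LOQ of 0.1200
        assert 0.0396 * 10 / 3.3 == pytest.approx(0.1200, abs=5e-5)

    def test_collinear_spectra_rejected(self):
        S = np.column_stack([np.ones(5), 2 * np.ones(5)])
        with pytest.raises(ValidationError, match="net analyte signal"):
            cc.nas_figures_of_merit(S, 0, noise_sd=0.01)


class TestRecoveryTtest:
    def test_exact_recoveries_give_zero_statistic(self):
        res = cc.recovery_ttest(np.full(13, 100.0))
        assert res["t"] == 0.0

    def test_critical_values_at_df_12(self):
        res = cc.recovery_ttest(np.linspace(98, 102, 13))
        assert res["df"] == 12
        assert res["critical"][0.025] == pytest.approx(2.179, abs=5e-4)
        assert res["critical"][0.01] == pytest.approx(2.681, abs=5e-4)

    def test_zero_spread_off_target_flags_infinity(self):
        res = cc.recovery_ttest(np.full(5, 99.0))
        assert np.isinf(res["t"])


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = np.array([1.0, 2.0, 3.0])
        res = cc.oneway_anova([g, g, g])
        assert res["F"] == 0.0

    def test_hand_computed_table(self):
        res = cc.oneway_anova(
            [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([3.0, 4, 5])]
        )
        assert res["F"] == pytest.approx(3.0)
        assert res["ms_between"] == pytest.approx(3.0)
        assert res["ms_within"] == pytest.approx(1.0)
        assert res["df"] == (2, 6)

    def test_location_shift_invariance_and_scipy_agreement(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(100, 2, 7) for _ in range(3)]
        r1 = cc.oneway_anova(groups)
        r2 = cc.oneway_anova([g + 17.3 for g in groups])
        assert r1["F"] == pytest.approx(r2["F"])
        ref = stats.f_oneway(*groups)
        assert r1["F"] == pytest.approx(ref.statistic)
        assert r1["p_value"] == pytest.approx(ref.pvalue)


class TestEjcr:
    def test_perfect_agreement_degenerates_to_ideal_point(self):
        y = np.array([1.0, 2, 3, 4, 5])
        res = cc.ejcr(pset(y, y))
        assert res.zero_area
        assert res.contains_ideal
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_large_offset_excludes_ideal_point(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(1, 10, 13)
        res = cc.ejcr(pset(y, y + 10 + rng.normal(0, 0.05, 13)))
        assert not res.contains_ideal

    def test_halving_noise_shrinks_the_ellipse(self):
        rng = np.random.default_rng(2)
        y = np.linspace(1, 10, 13)
        e = rng.normal(0, 1, 13)
        big = cc.ejcr(pset(y, y + 0.2 * e))
        small = cc.ejcr(pset(y, y + 0.1 * e))
        assert small.area < big.area

    def test_empirical_coverage_is_nominal(self):
        """Unbiased predictions fall inside the 95% region ~95% of the time."""
        rng = np.random.default_rng(42)
        hits = 0
        n_sets = 1000
        for _ in range(n_sets):
            y = rng.uniform(1, 10, 13)
            res = cc.ejcr(pset(y, y + rng.normal(0, 0.1, 13)))
            hits += res.contains_ideal
        assert hits / n_sets == pytest.approx(0.95, abs=0.02)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValidationError):
            cc.ejcr(pset([2.0, 2, 2], [1.9, 2.1, 2]))


class TestMatrixEffect:
    def test_identical_predictions_mean_no_effect(self):
        res = cc.matrix_effect([5.0, 10.0], [5.0, 10.0])
        np.testing.assert_allclose(res.mf, 1.0)
        np.testing.assert_allclose(res.me_percent, 0.0)

    @pytest.mark.parametrize("mf,me", [(0.9765, -2.35), (0.9873, -1.27)])
    def test_percent_effect_from_matrix_factor(self, mf, me):
        res = cc.matrix_effect([mf], [1.0])
        assert res.me_percent[0] == pytest.approx(me, abs=5e-3)

    def test_zero_neat_prediction_rejected(self):
        with pytest.raises(ValidationError):
            cc.matrix_effect([1.0], [0.0])
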