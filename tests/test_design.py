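"""Multilevel calibration grids and D-optimal Fedorov selection."""

import itertools

import numpy as np
import pytest

import chemocal as cc
from chemocal.datasets import ConfigurationError, ValidationError
from chemocal.design import InformationModel, leverage_diagnostics


def det_of(model, points):
    X = model.expand(points)
    return float(np.linalg.det(X.T @ X))


def brute_force_best(model, candidates, n_select):
    return max(
        det_of(model, candidates[list(c)])
        for c in itertools.combinations(range(len(candidates)), n_select)
    )


class TestBrereton:
    def test_default_five_level_grid(self, calib_design):
        assert calib_design.n_points == 25
        cfpm = sorted(set(calib_design.points[:, 0]))
        tazo = sorted(set(calib_design.points[:, 1]))
        assert cfpm == [1.0, 5.0, 9.0, 13.0, 17.0]
        assert tazo == [1.0, 3.0, 5.0, 7.0, 9.0]
        # level 0 sits at the range centre
        assert 9.0 in cfpm and 5.0 in tazo
        # full factorial: every pair appears exactly once
        pairs = {tuple(p) for p in calib_design.points}
        assert len(pairs) == 25

    def test_three_level_grid_hits_range_ends(self):
        dom = cc.ConcentrationDomain({"A": (1.0, 9.0), "B": (1.0, 9.0)})
        ds = cc.generate_brereton(dom, levels=3)
        assert ds.n_points == 9
        for col in range(2):
            assert ds.points[:, col].min() == 1.0
            assert ds.points[:, col].max() == 9.0

    def test_even_level_count_rejected(self):
        with pytest.raises(ConfigurationError):
            cc.generate_brereton(cc.DEFAULT_DOMAIN, levels=4)


class TestCandidates:
    def test_default_lattice_counts(self, calib_design):
        pool = cc.enumerate_candidates(cc.DEFAULT_DOMAIN, 1.0)
        assert pool.shape == (17 * 9, 2)
        pool_x = cc.enumerate_candidates(cc.DEFAULT_DOMAIN, 1.0, exclude=calib_design)
        assert pool_x.shape == (153 - 25, 2)

    def test_step_larger_than_range_degenerates_to_one_point_per_axis(self):
        pool = cc.enumerate_candidates(cc.DEFAULT_DOMAIN, 100.0)
        assert pool.shape == (1, 2)

    def test_empty_pool_after_exclusion_rejected(self):
        dom = cc.ConcentrationDomain({"A": (1.0, 2.0), "B": (1.0, 2.0)})
        full = cc.enumerate_candidates(dom, 1.0)
        ds = cc.DesignSet("calibration", ["A", "B"], full)
        with pytest.raises(ValidationError):
            cc.enumerate_candidates(dom, 1.0, exclude=ds)


class TestFedorov:
    # 4 corners + center + one interior point of the unit square
    TOY = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5], [0.3, 0.7]], float)

    def test_toy_matches_exhaustive_search(self):
        model = InformationModel("linear")
        ds, trace = cc.fedorov_select(self.TOY, 3, model, seed=0, restarts=5)
        got = det_of(model, ds.points)
        assert got == pytest.approx(1.0)
        assert got == pytest.approx(brute_force_best(model, self.TOY, 3))
        # only corners form the saturated optimum
        assert all(tuple(p) in {(0, 0), (1, 0), (0, 1), (1, 1)} for p in ds.points)

    def test_select_everything_means_no_swaps(self):
        model = InformationModel("linear")
        ds, trace = cc.fedorov_select(self.TOY, 6, model, seed=1, restarts=3)
        assert ds.n_points == 6
        assert trace.swaps == []
        assert trace.final_log_det == pytest.approx(
            np.linalg.slogdet(model.expand(self.TOY).T @ model.expand(self.TOY))[1]
        )

    def test_determinant_nondecreasing_within_restart(self):
        rng = np.random.default_rng(0)
        cand = rng.uniform(0, 1, size=(40, 2))
        _, trace = cc.fedorov_select(cand, 8, InformationModel("quadratic"), seed=3,
                                     restarts=1)
        dets = [s["log_det"] for s in trace.swaps]
        assert all(b >= a - 1e-9 for a, b in zip(dets, dets[1:]))

    def test_n_select_below_feature_count_rejected(self):
        with pytest.raises(ValidationError):
            cc.fedorov_select(self.TOY, 2, InformationModel("linear"))

    @pytest.mark.parametrize("seed", range(10))
    def test_exchange_attains_exhaustive_optimum_small_problems(self, seed):
        rng = np.random.default_rng(seed)
        cand = rng.uniform(-1, 1, size=(11, 2))
        model = InformationModel("quadratic")
        ds, _ = cc.fedorov_select(cand, 6, model, seed=seed, restarts=5)
        best = brute_force_best(model, cand, 6)
        assert det_of(model, ds.points) >= best * (1 - 1e-9)

    def test_default_selection_dominates_random_subsets(self, calib_design):
        model = InformationModel("quadratic", cc.DEFAULT_DOMAIN)
        cands = cc.enumerate_candidates(cc.DEFAULT_DOMAIN, 1.0, exclude=calib_design)
        ds, _ = cc.fedorov_select(cands, 13, model, seed=7, restarts=20)
        d_star = det_of(model, ds.points)
        rng = np.random.default_rng(1)
        for _ in range(200):
            sub = cands[rng.choice(len(cands), 13, replace=False)]
            assert d_star >= det_of(model, sub) * (1 - 1e-9)

    def test_validation_disjoint_from_calibration(self, calib_design, validation_design):
        cal = {tuple(p) for p in calib_design.points}
        val = {tuple(p) for p in validation_design.points}
        assert len(val) == 13
        assert cal.isdisjoint(val)

    def test_scale_invariance_of_selected_points(self, calib_design):
        """Affinely rescaling the domain must not change which points win."""
        model = InformationModel("quadratic", cc.DEFAULT_DOMAIN)
        cands = cc.enumerate_candidates(cc.DEFAULT_DOMAIN, 1.0, exclude=calib_design)
        ds1, _ = cc.fedorov_select(cands, 13, model, seed=2, restarts=5)

        scaled_dom = cc.ConcentrationDomain({"CFPM": (10.0, 170.0), "TAZO": (10.0, 90.0)})
        model2 = InformationModel("quadratic", scaled_dom)
        ds2, _ = cc.fedorov_select(cands * 10.0, 13, model2, seed=2, restarts=5)
        np.testing.assert_allclose(ds2.points, ds1.points * 10.0, atol=1e-9)


class TestLeverage:
    def test_leverages_sum_to_feature_count(self):
        rng = np.random.default_rng(5)
        ds = cc.DesignSet("validation", ["A", "B"], rng.uniform(0, 1, size=(9, 2)))
        res = leverage_diagnostics(ds, InformationModel("linear"))
        assert res["leverage_sum"] == pytest.approx(3.0)

    def test_saturated_corner_design_has_unit_leverages(self):
        ds = cc.DesignSet("validation", ["A", "B"], [[0, 0], [1, 0], [0, 1]])
        res = leverage_diagnostics(ds, InformationModel("linear"))
        np.testing.assert_allclose(res["leverages"], 1.0, atol=1e-12)

    def test_duplicated_points_share_leverage(self):
        ds = cc.DesignSet(
            "validation", ["A", "B"], [[0, 0], [0, 0], [1, 0], [0, 1]]
        )
        res = leverage_diagnostics(ds, InformationModel("linear"))
        assert res["leverages"][0] == pytest.approx(res["leverages"][1])
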