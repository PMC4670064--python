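"""Maxent core: feature expansion, oracle-checked fitting, prediction,
importance, response curves, AICc ranking."""

import numpy as np
import pandas as pd
import pytest

from nicheshift.maxent import (MaxentModel, ModelCandidate, aicc, aicc_rank,
                               build_feature_matrix, count_interior_modes,
                               fit_maxent, logistic_suitability, predict_raster,
                               raw_probabilities, response_curve,
                               variable_importance)
from nicheshift.raster import RasterStack

from conftest import make_grid


@pytest.fixture()
def six_cell():
    """Six background cells with one linear feature; presences on the warm end."""
    bg = pd.DataFrame({"x": np.linspace(0.0, 10.0, 6)})
    pres = pd.DataFrame({"x": [8.0, 9.0, 10.0, 9.5]})
    bdm, expander = build_feature_matrix(bg, classes=("linear",))
    return bg, pres, bdm, expander


class TestFeatures:
    def test_feature_counts_lqp(self):
        env = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [3.0, 5.0, 4.0]})
        dm, exp = build_feature_matrix(env, classes=("linear", "quadratic", "product"))
        assert dm.shape == (3, 5)        # 2 linear + 2 quadratic + 1 product

    def test_hinge_counts_both_directions(self):
        env = pd.DataFrame({"a": np.linspace(0, 1, 20)})
        dm, exp = build_feature_matrix(env, classes=("hinge",), n_hinge_knots=50)
        assert dm.shape == (20, 100)
        assert all(0 < s.knot < 1 for s in exp.specs)

    def test_constant_background_column_dropped(self):
        env = pd.DataFrame({"a": np.linspace(0, 1, 5), "b": np.ones(5)})
        with pytest.warns(UserWarning, match="constant"):
            dm, exp = build_feature_matrix(env, classes=("linear",))
        assert dm.shape == (5, 1)

    def test_product_with_one_variable_warns(self):
        env = pd.DataFrame({"a": np.linspace(0, 1, 5)})
        with pytest.warns(UserWarning, match="product"):
            dm, exp = build_feature_matrix(env, classes=("linear", "product"))
        assert dm.shape == (5, 1)

    def test_scaling_bounds_come_from_background(self):
        env = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        _, exp = build_feature_matrix(env, classes=("linear",))
        assert exp.bounds["a"] == (2.0, 6.0)
        z = exp.transform(pd.DataFrame({"a": [8.0]}))
        assert z[0, 0] == pytest.approx(1.5)       # beyond bounds unless clamped
        zc = exp.transform(pd.DataFrame({"a": [8.0]}), clamp=True)
        assert zc[0, 0] == 1.0


class TestFit:
    def test_total_shrinkage_at_huge_beta(self, six_cell):
        bg, pres, bdm, exp = six_cell
        m = fit_maxent(exp.transform(pres), bdm, beta=1e6, expander=exp)
        assert np.allclose(m.lam, 0.0)
        q = raw_probabilities(m, bdm)
        assert np.allclose(q, 1.0 / 6.0)

    def test_informative_binary_feature_positive_coefficient(self):
        bg = pd.DataFrame({"x": [0.0] * 5 + [1.0] * 5})
        pres = pd.DataFrame({"x": [1.0] * 4})
        bdm, exp = build_feature_matrix(bg, classes=("linear",))
        m = fit_maxent(exp.transform(pres), bdm, beta=0.5, expander=exp)
        assert m.lam[0] > 0

    def test_six_cell_grid_search_oracle(self, six_cell):
        """Fitted coefficient matches brute-force search of the penalized
        likelihood on a 1e-4 grid."""
        bg, pres, bdm, exp = six_cell
        m = fit_maxent(exp.transform(pres), bdm, beta=1.0, expander=exp)
        s = m.reg_scales[0]
        f_bg = bdm[:, 0]
        f_mean = exp.transform(pres)[:, 0].mean()

        def penalized(lam):
            return np.log(np.mean(np.exp(f_bg * lam))) - f_mean * lam + s * abs(lam)

        grid = np.arange(-10.0, 10.0, 1e-4)
        oracle = grid[np.argmin([penalized(l) for l in grid])]
        assert m.lam[0] == pytest.approx(oracle, abs=1e-3)

    def test_moment_matching_at_beta_zero(self):
        """With no penalty and linear features, background expectation of
        every feature under q equals its presence mean."""
        rng = np.random.default_rng(0)
        bg = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        pres = bg.iloc[rng.choice(50, 12, replace=False)] + 0.1
        bdm, exp = build_feature_matrix(bg, classes=("linear",))
        pdm = exp.transform(pres)
        m = fit_maxent(pdm, bdm, beta=0.0, expander=exp, tol=1e-12)
        q = raw_probabilities(m, bdm)
        for j in range(bdm.shape[1]):
            assert (q * bdm[:, j]).sum() == pytest.approx(pdm[:, j].mean(), abs=1e-6)

    def test_objective_trace_monotone_nonincreasing(self, six_cell):
        bg, pres, bdm, exp = six_cell
        m = fit_maxent(exp.transform(pres), bdm, beta=1.0, expander=exp)
        assert np.all(np.diff(m.objective_trace) <= 1e-12)

    def test_rejects_too_few_presences(self, six_cell):
        bg, pres, bdm, exp = six_cell
        with pytest.raises(ValueError):
            fit_maxent(exp.transform(pres)[:1], bdm, expander=exp)


class TestPrediction:
    def _fitted(self):
        rng = np.random.default_rng(1)
        bg = pd.DataFrame({"a": rng.uniform(0, 10, 100), "b": rng.uniform(0, 5, 100)})
        pres = pd.DataFrame({"a": rng.uniform(6, 10, 20), "b": rng.uniform(0, 2, 20)})
        bdm, exp = build_feature_matrix(bg, classes=("linear", "quadratic"))
        m = fit_maxent(exp.transform(pres), bdm, beta=1.0, expander=exp)
        return m, bg, pres

    def test_raw_sums_to_one_over_background(self, six_cell):
        bg, pres, bdm, exp = six_cell
        m = fit_maxent(exp.transform(pres), bdm, beta=1.0, expander=exp)
        assert raw_probabilities(m, bdm).sum() == pytest.approx(1.0, abs=1e-12)

    def test_raw_increasing_in_eta(self):
        m, bg, _ = self._fitted()
        dm = m.expander.transform(bg)
        eta = dm @ m.lam
        q = raw_probabilities(m, dm)
        order = np.argsort(eta)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_logistic_uniform_model_is_half(self):
        bg = pd.DataFrame({"x": np.linspace(0, 1, 8)})
        pres = pd.DataFrame({"x": [0.5, 0.6]})
        bdm, exp = build_feature_matrix(bg, classes=("linear",))
        m = fit_maxent(exp.transform(pres), bdm, beta=1e9, expander=exp)
        assert np.allclose(logistic_suitability(m, bg), 0.5)

    def test_logistic_in_unit_interval_and_rank_preserving(self):
        m, bg, _ = self._fitted()
        s = logistic_suitability(m, bg)
        eta = m.eta(bg)
        assert np.all((s > 0) & (s < 1))
        assert np.array_equal(np.argsort(s), np.argsort(eta, kind="stable"))

    def test_predict_raster_matches_pointwise(self):
        m, bg, _ = self._fitted()
        side = 10
        stack = RasterStack({
            "a": make_grid(bg["a"].to_numpy().reshape(side, side)),
            "b": make_grid(bg["b"].to_numpy().reshape(side, side)),
        })
        pred = predict_raster(m, stack, clamp=True)
        expected = logistic_suitability(m, bg, clamp=True).reshape(side, side)
        assert np.allclose(pred.values, expected, atol=1e-12)

    def test_clamped_prediction_equals_bound(self):
        m, bg, _ = self._fitted()
        hi = pd.DataFrame({"a": [m.expander.bounds["a"][1]], "b": [1.0]})
        beyond = pd.DataFrame({"a": [m.expander.bounds["a"][1] + 100], "b": [1.0]})
        assert logistic_suitability(m, beyond, clamp=True)[0] == pytest.approx(
            logistic_suitability(m, hi, clamp=True)[0])

    def test_nodata_propagates_and_clamp_idempotent(self):
        m, bg, _ = self._fitted()
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True
        stack = RasterStack({
            "a": make_grid(bg["a"].to_numpy().reshape(10, 10), mask=mask),
            "b": make_grid(bg["b"].to_numpy().reshape(10, 10)),
        })
        p1 = predict_raster(m, stack, clamp=True)
        assert np.isnan(p1.values[0, 0])
        # applying the model to its own (clamped) prediction inputs changes nothing
        p2 = predict_raster(m, stack, clamp=True)
        assert np.array_equal(p1.values, p2.values, equal_nan=True)

    def test_missing_layer_is_hard_error(self):
        m, bg, _ = self._fitted()
        stack = RasterStack({"a": make_grid(bg["a"].to_numpy().reshape(10, 10))})
        with pytest.raises(KeyError, match="b"):
            predict_raster(m, stack)

    def test_serialization_round_trip(self):
        m, bg, _ = self._fitted()
        back = MaxentModel.from_json(m.to_json())
        assert np.allclose(back.lam, m.lam)
        assert np.allclose(logistic_suitability(back, bg), logistic_suitability(m, bg))


class TestImportance:
    def test_single_variable_is_everything(self):
        rng = np.random.default_rng(2)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 80)})
        pres = pd.DataFrame({"a": rng.uniform(0.7, 1.0, 15)})
        bdm, exp = build_feature_matrix(bg, classes=("linear",))
        m = fit_maxent(exp.transform(pres), bdm, beta=0.5, expander=exp)
        vi = variable_importance(m, pres, bg, seed=0)
        assert vi.loc["a", "percent_contribution"] == pytest.approx(100.0)

    def test_duplicated_informative_variables_split_evenly(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 400)
        bg = pd.DataFrame({"a": x, "b": x.copy()})
        sel = rng.uniform(0.75, 1.0, 60)
        pres = pd.DataFrame({"a": sel, "b": sel.copy()})
        bdm, exp = build_feature_matrix(bg, classes=("linear",))
        m = fit_maxent(exp.transform(pres), bdm, beta=0.5, expander=exp)
        vi = variable_importance(m, pres, bg, seed=1, n_permutations=10)
        assert vi.loc["a", "percent_contribution"] == pytest.approx(50.0, abs=10.0)


class TestResponseCurves:
    def test_linear_model_monotone_no_interior_modes(self):
        rng = np.random.default_rng(4)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 100)})
        pres = pd.DataFrame({"a": rng.uniform(0.6, 1.0, 20)})
        bdm, exp = build_feature_matrix(bg, classes=("linear",))
        m = fit_maxent(exp.transform(pres), bdm, beta=0.5, expander=exp)
        xs, s, modes = response_curve(m, "a", bg)
        assert modes == 0
        assert np.all(np.diff(s) >= -1e-12)

    def test_quadratic_optimum_gives_one_interior_mode(self):
        rng = np.random.default_rng(5)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 200)})
        pres = pd.DataFrame({"a": rng.normal(0.5, 0.05, 40).clip(0, 1)})
        bdm, exp = build_feature_matrix(bg, classes=("linear", "quadratic"))
        m = fit_maxent(exp.transform(pres), bdm, beta=0.5, expander=exp)
        _, _, modes = response_curve(m, "a", bg)
        assert modes == 1

    def test_mode_count_matches_brute_force_scan(self):
        y = np.array([0.1, 0.5, 0.2, 0.3, 0.9, 0.8, 0.85, 0.2])
        brute = sum(1 for i in range(1, len(y) - 1) if y[i] > y[i - 1] and y[i] > y[i + 1])
        assert count_interior_modes(y) == brute == 3


class TestAicc:
    def test_direct_arithmetic(self):
        # 2k - 2lnL + 2k(k+1)/(n-k-1) with k=3, n=30, lnL=-100
        assert aicc(-100.0, 3, 30) == pytest.approx(206.923, abs=5e-4)

    def test_undefined_when_k_too_large(self):
        assert np.isnan(aicc(-10.0, 29, 30))

    def _candidate(self, name, lam_nonzero, bg, pres):
        bdm, exp = build_feature_matrix(bg, classes=("linear",))
        m = fit_maxent(exp.transform(pres), bdm, beta=0.5, expander=exp)
        m.lam = np.asarray(lam_nonzero, float)
        return ModelCandidate(name=name, classes=("linear",), beta=0.5, model=m)

    def test_equal_likelihood_fewer_parameters_ranks_first(self):
        rng = np.random.default_rng(6)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 50), "b": rng.uniform(0, 1, 50)})
        pres = pd.DataFrame({"a": rng.uniform(0, 1, 10), "b": rng.uniform(0, 1, 10)})
        sparse = self._candidate("sparse", [0.0, 0.0], bg, pres)
        dense = self._candidate("dense", [0.0, 1e-7], bg, pres)
        dense.model.lam = np.array([0.0, 0.0])
        # give dense an extra nonzero coefficient with negligible effect
        dense.model.lam = np.array([0.0, 1e-6])
        ranked = aicc_rank([dense, sparse], pres, bg)
        assert ranked[0].name == "sparse"

    def test_excluded_when_k_exceeds_presences(self):
        rng = np.random.default_rng(7)
        bg = pd.DataFrame({f"v{i}": rng.uniform(0, 1, 40) for i in range(4)})
        pres = bg.iloc[:3]
        bdm, exp = build_feature_matrix(bg, classes=("linear",))
        m = fit_maxent(exp.transform(pres), bdm, beta=1e-4, expander=exp)
        m.lam = np.ones(4)
        c = ModelCandidate(name="over", classes=("linear",), beta=0.0, model=m)
        with pytest.raises(ValueError, match="all candidates excluded"):
            aicc_rank([c], pres, bg)
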