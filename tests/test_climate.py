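"""Bioclim derivation against an independent cell-wise oracle, degree-days
closed forms, and the collinearity screen."""

import numpy as np
import pandas as pd
import pytest

from nicheshift.climate import (compute_degree_days, correlation_matrix,
                                derive_bioclim, extract_env_values,
                                prune_collinear, DAYS_IN_MONTH)
from nicheshift.raster import RasterStack

from conftest import constant_monthly, make_grid, monthly_from_arrays


# ---- independent oracle: straight per-cell python, no shared code ---------

def bioclim_oracle_cell(tmin, tmax, tmean, prec):
    """All 19 summaries for one cell from 12-month lists, by direct formula."""
    out = {}
    out["bio1"] = sum(tmean) / 12
    out["bio2"] = sum(tmax[m] - tmin[m] for m in range(12)) / 12
    out["bio5"] = max(tmax)
    out["bio6"] = min(tmin)
    out["bio7"] = out["bio5"] - out["bio6"]
    out["bio3"] = out["bio2"] / out["bio7"] * 100 if out["bio7"] else float("nan")
    mu = out["bio1"]
    out["bio4"] = (sum((t - mu) ** 2 for t in tmean) / 12) ** 0.5 * 100
    out["bio12"] = sum(prec)
    out["bio13"] = max(prec)
    out["bio14"] = min(prec)
    pmu = out["bio12"] / 12
    psd = (sum((p - pmu) ** 2 for p in prec) / 12) ** 0.5
    out["bio15"] = psd / (1 + out["bio12"] / 12) * 100
    qp = [prec[i] + prec[(i + 1) % 12] + prec[(i + 2) % 12] for i in range(12)]
    qt = [(tmean[i] + tmean[(i + 1) % 12] + tmean[(i + 2) % 12]) / 3 for i in range(12)]
    wet, dry = qp.index(max(qp)), qp.index(min(qp))
    warm, cold = qt.index(max(qt)), qt.index(min(qt))
    out["bio8"], out["bio9"] = qt[wet], qt[dry]
    out["bio10"], out["bio11"] = qt[warm], qt[cold]
    out["bio16"], out["bio17"] = qp[wet], qp[dry]
    out["bio18"], out["bio19"] = qp[warm], qp[cold]
    return out


def test_bioclim_matches_cellwise_oracle():
    rng = np.random.default_rng(5)
    shape = (12, 11, 13)
    tmean = rng.normal(15, 8, shape)
    half_range = rng.uniform(1, 6, shape)
    tmin, tmax = tmean - half_range, tmean + half_range
    prec = rng.gamma(2.0, 40.0, shape)
    stack = derive_bioclim(monthly_from_arrays(tmin, tmax, tmean, prec))
    cells = rng.integers(0, [11, 13], size=(100, 2))
    for r, c in cells:
        expected = bioclim_oracle_cell(tmin[:, r, c].tolist(), tmax[:, r, c].tolist(),
                                       tmean[:, r, c].tolist(), prec[:, r, c].tolist())
        for name, val in expected.items():
            assert stack[name].values[r, c] == pytest.approx(val, abs=1e-9), name


def test_bioclim_constant_climate_closed_forms():
    stack = derive_bioclim(constant_monthly(tmin=20.0, tmax=30.0, prec=100.0))
    assert np.allclose(stack["bio2"].valid_values(), 10.0)   # mean diurnal range
    assert np.allclose(stack["bio4"].valid_values(), 0.0)    # no seasonality
    assert np.allclose(stack["bio17"].valid_values(), 300.0)  # every quarter sums 300
    assert np.allclose(stack["bio16"].valid_values(), 300.0)
    assert np.allclose(stack["bio12"].valid_values(), 1200.0)


def test_bioclim_rejects_missing_month():
    monthly = constant_monthly()
    with pytest.raises(ValueError, match="missing months"):
        type(monthly)(tmin=monthly.tmin[:11], tmax=monthly.tmax,
                      tmean=monthly.tmean, prec=monthly.prec)


class TestDegreeDays:
    def test_at_base_temperature_is_zero(self):
        months = [make_grid(np.full((3, 3), 10.0)) for _ in range(12)]
        assert np.allclose(compute_degree_days(months).valid_values(), 0.0)

    def test_constant_twenty_degrees(self):
        months = [make_grid(np.full((3, 3), 20.0)) for _ in range(12)]
        # 10 degrees above base on every one of 365 days
        assert np.allclose(compute_degree_days(months).valid_values(), 3650.0)

    def test_single_warm_july(self):
        arrays = [np.full((2, 2), 5.0) for _ in range(12)]
        arrays[6] = np.full((2, 2), 12.0)      # July: 31 days x 2 degrees
        months = [make_grid(a) for a in arrays]
        assert np.allclose(compute_degree_days(months).valid_values(), 62.0)

    def test_monotone_in_monthly_means(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 25, (12, 4, 4))
        dd0 = compute_degree_days([make_grid(a) for a in base]).values
        for m in range(12):
            bumped = base.copy()
            bumped[m] += 1.5
            dd1 = compute_degree_days([make_grid(a) for a in bumped]).values
            assert np.all(dd1 >= dd0 - 1e-12)


class TestCollinearityScreen:
    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        env = pd.DataFrame({"a": x, "b": x.copy(), "c": -x})
        corr = correlation_matrix(env)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        env = pd.DataFrame(rng.normal(size=(10_000, 4)), columns=list("abcd"))
        corr = correlation_matrix(env).to_numpy()
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_zero_variance_column_flagged(self):
        env = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = correlation_matrix(env)
        assert np.isnan(corr.loc["a", "b"])
        assert corr.loc["b", "b"] == 1.0

    def test_prune_keeps_one_of_identical_pair(self):
        corr = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["a", "b"])
        assert prune_collinear(corr, ["a", "b"]) == ["a"]

    def test_prune_retains_pair_below_threshold(self):
        corr = pd.DataFrame([[1.0, 0.79], [0.79, 1.0]],
                            index=["a", "b"], columns=["a", "b"])
        assert prune_collinear(corr, ["a", "b"]) == ["a", "b"]

    def test_prune_triple_correlated_keeps_highest_priority(self):
        corr = pd.DataFrame(0.9 * np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        np.fill_diagonal(corr.values, 1.0)
        assert prune_collinear(corr, ["b", "a", "c"]) == ["b"]

    def test_prune_is_idempotent(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(500, 3))
        env = pd.DataFrame({
            "a": base[:, 0], "b": base[:, 0] + 0.1 * base[:, 1],
            "c": base[:, 1], "d": base[:, 2],
        })
        corr = correlation_matrix(env)
        kept = prune_collinear(corr, list(env.columns))
        again = prune_collinear(corr.loc[kept, kept], kept)
        assert again == kept

    def test_empty_priority_uses_column_order(self):
        corr = pd.DataFrame([[1.0, 0.95], [0.95, 1.0]],
                            index=["y", "x"], columns=["y", "x"])
        assert prune_collinear(corr, []) == ["y"]


class TestExtraction:
    def _stack(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = True
        vals = np.arange(16, dtype=float).reshape(4, 4)
        return RasterStack({"v": make_grid(vals, mask=mask)})

    def test_point_at_cell_center(self):
        stack = self._stack()
        res = extract_env_values(["p"], [2.5], [1.5], stack)
        assert res.table.loc["p", "v"] == stack["v"].values[2, 2]

    def test_nodata_and_outside_dropped_with_reasons(self):
        stack = self._stack()
        res = extract_env_values(["good", "nodata", "out"],
                                 [0.5, 1.5, 99.0], [0.5, 2.5, 0.5], stack)
        assert list(res.table.index) == ["good"]
        reasons = dict(zip(res.dropped["id"], res.dropped["reason"]))
        assert reasons == {"nodata": "nodata cell", "out": "outside extent"}

    def test_all_points_dropped_is_an_error(self):
        with pytest.raises(ValueError, match="all points"):
            extract_env_values(["p"], [99.0], [99.0], self._stack())
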