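"""Bioclimatic predictor derivation and collinearity screening.

Builds the 20-variable predictor set used throughout the pipeline: the 19
standard bioclim summaries computed from monthly temperature and
precipitation grids, plus an annual degree-day sum above a 10 degC base
(a thermal-budget variable relevant to ectotherm establishment).

Conventions (fixed here so every dialect question has one answer):

* A "quarter" is any 3 consecutive calendar months, with wrap-around
  (Nov-Dec-Jan and Dec-Jan-Feb are quarters).  Wettest / driest / warmest /
  coldest quarters are the extreme windows; ties resolve to the earliest
  window.
* ``bio3`` (isothermality) = (bio2 / bio7) x 100.
* ``bio4`` (temperature seasonality) = population SD of the 12 monthly
  means x 100.
* ``bio15`` (precipitation seasonality) = SD of monthly precipitation
  divided by (1 + bio12/12), x 100.
* Degree-days use calendar month lengths in a 365-day (non-leap) year:
  sum over months of days_in_month x max(0, tmean_month - base).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterGrid, RasterStack

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: layer names of the full predictor set, in conventional order
BIOCLIM_NAMES = [f"bio{i}" for i in range(1, 20)] + ["degdays10"]


@dataclass
class MonthlyClimate:
    """Twelve monthly grids each of tmin/tmax/tmean (degC) and prec (mm)."""

    tmin: list[RasterGrid]
    tmax: list[RasterGrid]
    tmean: list[RasterGrid]
    prec: list[RasterGrid]

    def __post_init__(self):
        for name in ("tmin", "tmax", "tmean", "prec"):
            layers = getattr(self, name)
            if len(layers) != 12:
                missing = [m for m in range(1, 13) if m > len(layers)]
                raise ValueError(f"{name}: expected 12 monthly grids, missing months {missing}")
        frame = self.tmin[0]
        for layers in (self.tmin, self.tmax, self.tmean, self.prec):
            for g in layers:
                if not g.same_frame(frame):
                    raise ValueError("all monthly grids must share one frame")

    @property
    def frame(self) -> RasterGrid:
        return self.tmin[0]

    def arrays(self):
        """Stacked (12, nrows, ncols) arrays: tmin, tmax, tmean, prec, mask."""
        tmin = np.stack([g.values for g in self.tmin])
        tmax = np.stack([g.values for g in self.tmax])
        tmean = np.stack([g.values for g in self.tmean])
        prec = np.stack([g.values for g in self.prec])
        mask = np.zeros(self.frame.shape, dtype=bool)
        for layers in (self.tmin, self.tmax, self.tmean, self.prec):
            for g in layers:
                mask |= g.nodata_mask
        return tmin, tmax, tmean, prec, mask


def _quarter_windows():
    """Indices of the 12 wrap-around 3-month windows, window i starting at month i."""
    return [(i, (i + 1) % 12, (i + 2) % 12) for i in range(12)]


def _quarter_sums(monthly: np.ndarray) -> np.ndarray:
    """(12, ...) array of 3-month rolling sums with wrap-around."""
    return np.stack([monthly[list(w)].sum(axis=0) for w in _quarter_windows()])


def derive_bioclim(monthly: MonthlyClimate) -> RasterStack:
    """Compute bio1..bio19 and degdays10 from monthly climate.

    Returns a :class:`RasterStack` with the 20 named layers on the input
    frame; the nodata mask is the union of the monthly masks.
    """
    tmin, tmax, tmean, prec, mask = monthly.arrays()
    frame = monthly.frame
    with np.errstate(invalid="ignore", divide="ignore"):
        bio: dict[str, np.ndarray] = {}
        bio["bio1"] = tmean.mean(axis=0)
        bio["bio2"] = (tmax - tmin).mean(axis=0)
        bio["bio4"] = tmean.std(axis=0) * 100.0
        bio["bio5"] = tmax.max(axis=0)
        bio["bio6"] = tmin.min(axis=0)
        bio["bio7"] = bio["bio5"] - bio["bio6"]
        bio["bio3"] = np.where(bio["bio7"] != 0, bio["bio2"] / bio["bio7"] * 100.0, np.nan)
        bio["bio12"] = prec.sum(axis=0)
        bio["bio13"] = prec.max(axis=0)
        bio["bio14"] = prec.min(axis=0)
        bio["bio15"] = prec.std(axis=0) / (1.0 + bio["bio12"] / 12.0) * 100.0

        q_prec = _quarter_sums(prec)                      # precip totals per window
        q_temp = _quarter_sums(tmean) / 3.0               # mean temp per window
        wettest = q_prec.argmax(axis=0)
        driest = q_prec.argmin(axis=0)
        warmest = q_temp.argmax(axis=0)
        coldest = q_temp.argmin(axis=0)
        take = lambda arr, idx: np.take_along_axis(arr, idx[None], axis=0)[0]
        bio["bio8"] = take(q_temp, wettest)
        bio["bio9"] = take(q_temp, driest)
        bio["bio10"] = take(q_temp, warmest)
        bio["bio11"] = take(q_temp, coldest)
        bio["bio16"] = take(q_prec, wettest)
        bio["bio17"] = take(q_prec, driest)
        bio["bio18"] = take(q_prec, warmest)
        bio["bio19"] = take(q_prec, coldest)

    stack = RasterStack({})
    for name in BIOCLIM_NAMES[:-1]:
        stack.add(name, frame.copy_with(np.where(mask, np.nan, bio[name]), mask.copy()))
    stack.add("degdays10", compute_degree_days(monthly.tmean, base=10.0))
    return stack


def compute_degree_days(tmean_monthly: list[RasterGrid], base: float = 10.0) -> RasterGrid:
    """Annual degree-day sum above ``base``: sum_m days_m * max(0, tmean_m - base)."""
    if len(tmean_monthly) != 12:
        missing = [m for m in range(1, 13) if m > len(tmean_monthly)]
        raise ValueError(f"expected 12 monthly mean-temperature grids, missing months {missing}")
    tmean = np.stack([g.values for g in tmean_monthly])
    mask = np.zeros(tmean_monthly[0].shape, dtype=bool)
    for g in tmean_monthly:
        mask |= g.nodata_mask
    dd = (DAYS_IN_MONTH[:, None, None] * np.clip(tmean - base, 0.0, None)).sum(axis=0)
    return tmean_monthly[0].copy_with(np.where(mask, np.nan, dd), mask)


def correlation_matrix(env: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of an environment table.

    Columns with zero variance get NaN off-diagonal entries (r undefined)
    and a warning; the diagonal is always 1.
    """
    if len(env) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    values = env.to_numpy(dtype=float)
    sd = values.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"zero-variance columns, correlation undefined: {list(env.columns[constant])}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=env.columns, columns=env.columns)


def prune_collinear(
    corr: pd.DataFrame,
    keep_priority: list[str] | None = None,
    threshold: float = 0.80,
) -> list[str]:
    """Greedy collinearity screen: keep a variable only if |r| < threshold
    against everything already kept, walking the priority order.

    Variables absent from ``keep_priority`` are appended in column order.
    Pairs with undefined correlation (constant columns) do not block
    retention.  The result is idempotent under re-pruning.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    cols = list(corr.columns)
    order = [v for v in (keep_priority or []) if v in cols]
    order += [v for v in cols if v not in order]
    kept: list[str] = []
    for v in order:
        r = corr.loc[v, kept].to_numpy(dtype=float) if kept else np.array([])
        if not np.any(np.abs(r) >= threshold):
            kept.append(v)
    return kept


@dataclass
class ExtractionResult:
    """Environment table plus a report of points dropped during extraction."""

    table: pd.DataFrame          # index = point id, columns = layer names
    dropped: pd.DataFrame        # columns: id, reason
    rows: np.ndarray             # grid row per retained point
    cols: np.ndarray             # grid col per retained point


def extract_env_values(
    ids, x, y, stack: RasterStack, names: list[str] | None = None
) -> ExtractionResult:
    """Nearest-cell lookup of stack values at points.

    Points outside the grid extent or on nodata cells are dropped and listed
    in the report; an empty retained set raises.
    """
    names = names or stack.names
    frame = stack.frame
    ids = np.asarray(ids)
    row, col = frame.cell_index(np.asarray(x, float), np.asarray(y, float))
    inside = frame.in_bounds(row, col)
    mask = stack.combined_mask()
    ok = inside.copy()
    ok[inside] &= ~mask[row[inside], col[inside]]

    reasons = np.where(~inside, "outside extent", np.where(~ok, "nodata cell", ""))
    dropped = pd.DataFrame({"id": ids[~ok], "reason": reasons[~ok]})
    if not ok.any():
        raise ValueError("all points fell outside the grid or on nodata cells")
    r, c = row[ok], col[ok]
    data = {n: stack[n].values[r, c] for n in names}
    table = pd.DataFrame(data, index=pd.Index(ids[ok], name="id"))
    return ExtractionResult(table=table, dropped=dropped, rows=r, cols=c)
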