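"""Occurrence ingestion, filtering and background sampling.

Presence records are carried as a table (id, species, longitude, latitude,
range_label, source) wrapped with a provenance log: every filtering step
appends one entry recording input / retained / removed counts, so the
record trail from raw compilation to modelling set reconciles exactly.

Coordinates on grids tagged ``WGS84`` are geographic degrees and are
projected to the cylindrical equal-area plane before any distance
computation; grids with other tags (synthetic landscapes) are treated as
already planar with coordinates in kilometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import RasterGrid, equal_area_xy

RANGE_LABELS = {"native", "invasive_conus", "invasive_nonconus"}
REQUIRED_COLUMNS = ["id", "species", "longitude", "latitude", "range_label", "source"]

#: floor for bias weights on accessible cells — keeps every cell drawable
BIAS_FLOOR = 1e-6


def metric_xy(lon, lat, crs_tag: str = "WGS84"):
    """Coordinates in km on an equal-area plane (projecting if geographic)."""
    if crs_tag.upper().startswith("WGS84"):
        x, y = equal_area_xy(lon, lat)
        return x / 1000.0, y / 1000.0
    return np.asarray(lon, float), np.asarray(lat, float)


@dataclass
class OccurrenceSet:
    """Georeferenced presences with range labels and a filtering provenance log."""

    records: pd.DataFrame
    log: list[dict] = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"occurrence table missing required columns: {missing}")
        if self.records["id"].duplicated().any():
            dup = self.records.loc[self.records["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate occurrence ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def log_step(self, step: str, n_input: int, n_retained: int, **detail) -> None:
        self.log.append(
            {"step": step, "n_input": int(n_input), "n_retained": int(n_retained),
             "n_removed": int(n_input - n_retained), **detail}
        )

    def subset(self, keep_mask: np.ndarray, step: str, **detail) -> "OccurrenceSet":
        """New set with rows where keep_mask, carrying the log forward."""
        out = OccurrenceSet(self.records.loc[keep_mask].reset_index(drop=True),
                            log=list(self.log))
        out.log_step(step, len(self), int(np.sum(keep_mask)), **detail)
        return out

    def for_range(self, *labels: str) -> "OccurrenceSet":
        keep = self.records["range_label"].isin(labels).to_numpy()
        return self.subset(keep, "range_filter", labels=list(labels))

    def xy_km(self, crs_tag: str = "WGS84"):
        return metric_xy(self.records["longitude"].to_numpy(),
                         self.records["latitude"].to_numpy(), crs_tag)


def read_occurrences(path) -> OccurrenceSet:
    """Parse an occurrence CSV, rejecting malformed rows with their numbers.

    A missing required column is a hard error; bad coordinates or an unknown
    range label reject only that row (reported via warning and the log).
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=REQUIRED_COLUMNS)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence file {path} missing required column(s): {missing}")
    if df.empty:
        warnings.warn(f"occurrence file {path} contains no records")
        occ = OccurrenceSet(df)
        occ.log_step("read", 0, 0, path=str(path))
        return occ

    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    ok = (
        lon.between(-180, 180)
        & lat.between(-90, 90)
        & df["range_label"].isin(RANGE_LABELS)
        & df["id"].notna()
    )
    bad_rows = (df.index[~ok] + 2).tolist()  # 1-based with header line
    if bad_rows:
        warnings.warn(f"rejected {len(bad_rows)} malformed occurrence rows (file lines {bad_rows})")
    records = df.loc[ok].copy()
    records["longitude"] = lon[ok]
    records["latitude"] = lat[ok]
    occ = OccurrenceSet(records.reset_index(drop=True))
    occ.log_step("read", len(df), len(records), path=str(path), rejected_lines=bad_rows)
    return occ


def dedupe_to_grid(occ: OccurrenceSet, grid: RasterGrid) -> OccurrenceSet:
    """Keep at most one record per grid cell (first by input order)."""
    row, col = grid.cell_index(occ.records["longitude"].to_numpy(),
                               occ.records["latitude"].to_numpy())
    cell = pd.Series(list(zip(row, col)))
    keep = ~cell.duplicated().to_numpy()
    return occ.subset(keep, "dedupe_to_grid", cell_size=grid.cell_size)


def spatial_thin(occ: OccurrenceSet, min_dist_km: float, seed: int,
                 crs_tag: str = "WGS84") -> OccurrenceSet:
    """Greedy spatial thinning to a minimum pairwise distance.

    Repeatedly drops the record with the most neighbours closer than
    ``min_dist_km`` (ties broken by a seeded draw) until no pair violates
    the distance — the maximal-retention heuristic used by standard
    thinning tools.  Deterministic for a fixed seed.
    """
    if min_dist_km <= 0:
        raise ValueError("min_dist_km must be positive")
    n = len(occ)
    if n <= 1:
        return occ.subset(np.ones(n, bool), "spatial_thin", min_dist_km=min_dist_km)
    x, y = occ.xy_km(crs_tag)
    d2 = (x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2
    close = d2 < min_dist_km**2
    np.fill_diagonal(close, False)
    rng = np.random.default_rng(seed)
    alive = np.ones(n, dtype=bool)
    while True:
        counts = (close & alive[None, :]).sum(axis=1)
        counts[~alive] = 0
        worst = counts.max()
        if worst == 0:
            break
        candidates = np.flatnonzero(alive & (counts == worst))
        alive[rng.choice(candidates)] = False
    return occ.subset(alive, "spatial_thin", min_dist_km=min_dist_km, seed=seed)


def bias_surface(occ: OccurrenceSet, grid: RasterGrid, bandwidth_km: float) -> RasterGrid:
    """Gaussian kernel density of sampling effort, rescaled to max 1.

    The occurrence count raster is smoothed with a Gaussian kernel whose
    bandwidth is expressed in km and converted to cells using the grid's
    metric cell size (evaluated at the grid centre for geographic grids).
    Weights are floored at 1e-6 on valid cells so no cell is unreachable.
    """
    vals = np.zeros(grid.shape)
    if len(occ) == 0:
        warnings.warn("no occurrences: bias surface is uniform")
        vals[:] = 1.0
        return grid.copy_with(np.where(grid.nodata_mask, np.nan, vals))
    row, col = grid.cell_index(occ.records["longitude"].to_numpy(),
                               occ.records["latitude"].to_numpy())
    inside = grid.in_bounds(row, col)
    np.add.at(vals, (row[inside], col[inside]), 1.0)
    sigma_cells = bandwidth_km / _cell_km(grid)
    vals = ndimage.gaussian_filter(vals, sigma=sigma_cells, mode="constant")
    vals = vals / vals.max()
    vals = np.maximum(vals, BIAS_FLOOR)
    return grid.copy_with(np.where(grid.nodata_mask, np.nan, vals))


def _cell_km(grid: RasterGrid) -> float:
    """Metric cell edge in km (geometric mean of x/y spacing for geographic grids)."""
    if not grid.crs_tag.upper().startswith("WGS84"):
        return grid.cell_size
    lat_c = grid.y_origin - grid.n_rows * grid.cell_size / 2.0
    x0, y0 = metric_xy(0.0, lat_c - grid.cell_size / 2.0)
    x1, y1 = metric_xy(grid.cell_size, lat_c + grid.cell_size / 2.0)
    dx, dy = abs(x1 - x0), abs(y1 - y0)
    return float(np.sqrt(dx * dy))


@dataclass
class BackgroundSample:
    """Cells drawn from the accessible area, with the weights used to draw them."""

    rows: np.ndarray
    cols: np.ndarray
    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray
    seed: int


def sample_background(mask: RasterGrid, n: int = 50_000,
                      bias: RasterGrid | None = None, seed: int = 0) -> BackgroundSample:
    """Draw background cells from the accessible area without replacement.

    ``mask`` marks accessible cells with 1.  Draw probability is
    proportional to the bias surface if given, else uniform.  If ``n``
    exceeds the number of accessible cells, all cells are returned with a
    warning.
    """
    accessible = (mask.values == 1) & ~mask.nodata_mask
    if bias is not None:
        if not bias.same_frame(mask):
            raise ValueError("bias surface must share the mask's grid frame")
        accessible &= ~bias.nodata_mask
    rows, cols = np.nonzero(accessible)
    if rows.size == 0:
        raise ValueError("accessible-area mask is empty")
    w = np.ones(rows.size) if bias is None else bias.values[rows, cols]
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    if n >= rows.size:
        if n > rows.size:
            warnings.warn(f"requested {n} background points but only "
                          f"{rows.size} accessible cells; returning all")
        idx = np.arange(rows.size)
    else:
        idx = rng.choice(rows.size, size=n, replace=False, p=w)
    r, c = rows[idx], cols[idx]
    x, y = mask.cell_center(r, c)
    return BackgroundSample(rows=r, cols=c, x=x, y=y, weights=w[idx], seed=seed)
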