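"""Gridded raster containers, text-grid I/O and the equal-area projection.

Rasters are stored row-major with row 0 at the *top* (northernmost) edge,
matching the ESRI ASCII grid convention used for on-disk exchange.  A
:class:`RasterGrid` couples a 2-D value array with a geotransform (origin of
the upper-left corner plus square cell size) and a boolean nodata mask; a
:class:`RasterStack` is an ordered set of layers sharing one grid frame.

Distances and kernel bandwidths are always computed in an equal-area frame:
geographic coordinates are projected with the World Cylindrical Equal Area
projection (standard parallel 0, WGS84 authalic radius) before any metric
operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# WGS84 authalic radius, metres: the sphere with the ellipsoid's surface area.
EARTH_RADIUS_M = 6_371_007.181


def equal_area_xy(lon, lat):
    """Project lon/lat (decimal degrees) to World Cylindrical Equal Area metres.

    x = R * lambda,  y = R * sin(phi)  — an exact equal-area cylindrical map
    with the equator as standard parallel.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = EARTH_RADIUS_M * np.radians(lon)
    y = EARTH_RADIUS_M * np.sin(np.radians(lat))
    return x, y


@dataclass
class RasterGrid:
    """One gridded variable: values + geotransform + nodata mask.

    Parameters
    ----------
    values : (n_rows, n_cols) float array
    x_origin, y_origin : float
        Coordinates of the *upper-left corner* of the upper-left cell.
    cell_size : float
        Square cell edge, in the units of the CRS (degrees or metres).
    nodata_mask : bool array, True where the cell carries no data.
    crs_tag : free-text identifier ("WGS84", "synthetic", ...).
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    nodata_mask: np.ndarray | None = None
    crs_tag: str = "WGS84"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata mask shape mismatch")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self):
        return self.values.shape

    def same_frame(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        """New grid on this frame with different values (mask defaults to self's)."""
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            cell_size=self.cell_size,
            nodata_mask=self.nodata_mask.copy() if mask is None else mask,
            crs_tag=self.crs_tag,
        )

    # ---- point <-> cell ----------------------------------------------------

    def cell_index(self, x, y):
        """Nearest-cell (row, col) for coordinate arrays; may be out of range."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - y) / self.cell_size).astype(int)
        return row, col

    def in_bounds(self, row, col):
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_center(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin - (row + 0.5) * self.cell_size
        return x, y

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    # ---- ESRI ASCII grid I/O ----------------------------------------------

    def write_ascii(self, path, nodata_value: float = -9999.0) -> None:
        vals = np.where(self.nodata_mask, nodata_value, self.values)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.x_origin!r}\n"
            f"yllcorner {(self.y_origin - self.n_rows * self.cell_size)!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {nodata_value!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path, crs_tag: str = "WGS84") -> "RasterGrid":
        header: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                pos = fh.tell()
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value",
                }:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    fh.seek(pos)
                    break
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        n_rows = int(header["nrows"])
        n_cols = int(header["ncols"])
        if vals.shape != (n_rows, n_cols):
            raise ValueError(
                f"grid body {vals.shape} does not match header ({n_rows}, {n_cols})"
            )
        cell = header["cellsize"]
        nodata = header.get("nodata_value", -9999.0)
        mask = np.isclose(vals, nodata) | ~np.isfinite(vals)
        return cls(
            values=np.where(mask, np.nan, vals),
            x_origin=header["xllcorner"],
            y_origin=header["yllcorner"] + n_rows * cell,
            cell_size=cell,
            nodata_mask=mask,
            crs_tag=crs_tag,
        )


@dataclass
class RasterStack:
    """Named raster layers sharing one grid frame; nodata is the union mask."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self):
        names = list(self.layers)
        for name in names[1:]:
            if not self.layers[name].same_frame(self.layers[names[0]]):
                raise ValueError(f"layer {name!r} is not on the shared grid frame")

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def frame(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def add(self, name: str, grid: RasterGrid) -> None:
        if self.layers and not grid.same_frame(self.frame):
            raise ValueError(f"layer {name!r} is not on the shared grid frame")
        self.layers[name] = grid

    def combined_mask(self) -> np.ndarray:
        mask = np.zeros(self.frame.shape, dtype=bool)
        for g in self.layers.values():
            mask |= g.nodata_mask
        return mask

    def table(self, names: list[str] | None = None) -> np.ndarray:
        """(n_valid_cells, n_layers) array over cells valid in every layer."""
        names = names or self.names
        mask = self.combined_mask()
        return np.column_stack([self.layers[n].values[~mask] for n in names])

    def write_dir(self, directory, nodata_value: float = -9999.0) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        for name, g in self.layers.items():
            g.write_ascii(os.path.join(directory, f"{name}.asc"), nodata_value)

    @classmethod
    def read_dir(cls, directory, names: list[str] | None = None) -> "RasterStack":
        import glob
        import os

        if names is None:
            names = sorted(
                os.path.splitext(os.path.basename(p))[0]
                for p in glob.glob(os.path.join(directory, "*.asc"))
            )
        layers = {
            n: RasterGrid.read_ascii(os.path.join(directory, f"{n}.asc")) for n in names
        }
        if not layers:
            raise FileNotFoundError(f"no .asc layers found in {directory}")
        return cls(layers)
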