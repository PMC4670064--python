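"""Shared fixtures: small synthetic studies and tiny hand-built rasters."""

import numpy as np
import pandas as pd
import pytest

from nicheshift.climate import MonthlyClimate
from nicheshift.raster import RasterGrid
from nicheshift.synth import VirtualSpeciesConfig, generate_invasion_study


def make_grid(values, cell_size=1.0, crs_tag="synthetic_km", mask=None):
    values = np.asarray(values, dtype=float)
    return RasterGrid(values=values, x_origin=0.0,
                      y_origin=values.shape[0] * cell_size, cell_size=cell_size,
                      nodata_mask=mask, crs_tag=crs_tag)


def constant_monthly(shape=(4, 5), tmin=20.0, tmax=30.0, prec=100.0):
    """Monthly climate with the same values every month (tmean = midpoint)."""
    tmean = (tmin + tmax) / 2.0
    mk = lambda v: [make_grid(np.full(shape, v)) for _ in range(12)]
    return MonthlyClimate(tmin=mk(tmin), tmax=mk(tmax), tmean=mk(tmean), prec=mk(prec))


def monthly_from_arrays(tmin, tmax, tmean, prec):
    """Build MonthlyClimate from (12, r, c) arrays."""
    mk = lambda a: [make_grid(a[m]) for m in range(12)]
    return MonthlyClimate(tmin=mk(tmin), tmax=mk(tmax), tmean=mk(tmean), prec=mk(prec))


@pytest.fixture(scope="session")
def small_study():
    """A ground-truthed 60x60 virtual-species study with a 1-SD niche shift."""
    cfg = VirtualSpeciesConfig(n_rows=60, n_cols=60, n_presences=80, delta=1.0, seed=11)
    return generate_invasion_study(cfg)


@pytest.fixture()
def occurrence_frame():
    return pd.DataFrame({
        "id": ["a", "b", "c"],
        "species": "virtualis",
        "longitude": [10.0, 10.5, 11.0],
        "latitude": [45.0, 45.2, 45.4],
        "range_label": ["native", "native", "invasive_conus"],
        "source": "test",
    })
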