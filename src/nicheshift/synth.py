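"""Virtual-species study generator.

Produces paired "native" and "invaded" synthetic landscapes with monthly
climate, a known (true) suitability surface on each, and presence samples
with controllable spatial sampling bias — the ground-truthed input for
exercising and validating the whole pipeline.

Landscape fields are band-limited sums of seeded sinusoids (smooth,
spatially autocorrelated, reproducible without FFT machinery).  The true
niche is a logistic of a quadratic form,

    s(x) = 1 / (1 + exp(-[a - sum_v ((x_v - mu_v)/sigma_v)^2])),

a unimodal Gaussian-like response on each predictor.  A niche shift of
magnitude ``delta`` (in pooled-background SD units) separates the two
ranges' optima along the first principal axis of the pooled background
climate, so the realized shift is aligned with — and recoverable from —
the PC1/PC2 space used by the niche-overlap analysis.

Coordinates are planar kilometres (crs_tag ``synthetic_km``); the default
study is a 200 x 200-cell landscape at 0.4 km resolution (80 km extent),
5 predictor variables and 250 presences per range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import climate as _climate
from .occurrences import OccurrenceSet, REQUIRED_COLUMNS
from .raster import RasterGrid, RasterStack


@dataclass
class VirtualSpeciesConfig:
    """Generator settings; every source of randomness flows from ``seed``."""

    n_rows: int = 200
    n_cols: int = 200
    cell_size_km: float = 0.4
    variables: tuple[str, ...] = ("bio1", "bio2", "bio4", "bio12", "bio15")
    smoothness: float = 0.25          # dominant wavelength as fraction of extent
    n_harmonics: int = 8
    seasonal_amplitude: float = 8.0   # degC annual swing of monthly means
    suit_intercept: float = 4.0       # "a" in the logistic quadratic form
    niche_breadth: float = 0.75       # sigma_v in background-SD units
    delta: float = 0.0                # niche-shift magnitude, background-SD units
    n_presences: int = 250
    bias_strength: float = 1.0        # exp(strength * east-west gradient) sampling bias
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("landscape must be at least 10 x 10 cells")
        if self.niche_breadth <= 0:
            raise ValueError("niche breadth must be positive")
        if self.n_presences < 1:
            raise ValueError("n_presences must be >= 1")


def _sinusoid_field(rng: np.random.Generator, shape, smoothness: float,
                    n_harmonics: int) -> np.ndarray:
    """Zero-mean unit-SD smooth field from superposed random plane waves."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    extent = max(rows, cols)
    f = np.zeros(shape)
    for _ in range(n_harmonics):
        wavelength = extent * smoothness * (0.5 + rng.random() * 1.5)
        theta = rng.random() * 2 * np.pi
        phase = rng.random() * 2 * np.pi
        amp = 0.5 + rng.random()
        k = 2 * np.pi / wavelength
        f += amp * np.sin(k * (np.cos(theta) * xx + np.sin(theta) * yy) + phase)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _grid(config: VirtualSpeciesConfig, values: np.ndarray) -> RasterGrid:
    return RasterGrid(
        values=values, x_origin=0.0,
        y_origin=config.n_rows * config.cell_size_km,
        cell_size=config.cell_size_km, crs_tag="synthetic_km",
        nodata_mask=np.zeros(values.shape, dtype=bool),
    )


def generate_landscape(config: VirtualSpeciesConfig, seed: int | None = None):
    """One landscape: monthly climate plus an all-accessible area mask.

    Monthly means follow an annual cosine cycle (July peak) around a
    smooth mean-temperature field; the diurnal range field keeps
    tmin <= tmean <= tmax everywhere; precipitation is a positive smooth
    field with its own seasonal cycle.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = (config.n_rows, config.n_cols)
    t_base = 18.0 + 6.0 * _sinusoid_field(rng, shape, config.smoothness, config.n_harmonics)
    t_season = config.seasonal_amplitude * (
        0.6 + 0.4 * _norm01(_sinusoid_field(rng, shape, config.smoothness, config.n_harmonics)))
    diurnal = 8.0 + 4.0 * _norm01(_sinusoid_field(rng, shape, config.smoothness, config.n_harmonics))
    p_base = 70.0 * np.exp(0.7 * _sinusoid_field(rng, shape, config.smoothness, config.n_harmonics))
    p_seasonality = _norm01(_sinusoid_field(rng, shape, config.smoothness, config.n_harmonics))
    p_peak_month = rng.integers(0, 12)

    months = np.arange(12)
    tmean_m, tmin_m, tmax_m, prec_m = [], [], [], []
    for m in months:
        cyc = np.cos(2 * np.pi * (m - 6) / 12.0)
        tm = t_base + t_season * cyc
        tmean_m.append(_grid(config, tm))
        tmin_m.append(_grid(config, tm - diurnal / 2.0))
        tmax_m.append(_grid(config, tm + diurnal / 2.0))
        pcyc = np.cos(2 * np.pi * (m - p_peak_month) / 12.0)
        prec_m.append(_grid(config, np.clip(p_base * (1.0 + 0.6 * p_seasonality * pcyc), 0.0, None)))
    monthly = _climate.MonthlyClimate(tmin=tmin_m, tmax=tmax_m, tmean=tmean_m, prec=prec_m)
    mask = _grid(config, np.ones(shape))
    return monthly, mask


def _norm01(f: np.ndarray) -> np.ndarray:
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros_like(f)


def true_suitability(stack: RasterStack, variables, mu: dict, sigma: dict,
                     intercept: float) -> RasterGrid:
    """Logistic quadratic-form suitability on the given stack."""
    for v in variables:
        if v not in stack:
            raise KeyError(f"stack missing suitability variable {v!r}")
    mask = stack.combined_mask()
    z2 = np.zeros(stack.frame.shape)
    for v in variables:
        z2 += ((stack[v].values - mu[v]) / sigma[v]) ** 2
    s = 1.0 / (1.0 + np.exp(-(intercept - z2)))
    return stack.frame.copy_with(np.where(mask, np.nan, s), mask.copy())


def sample_presences(suitability: RasterGrid, n: int,
                     bias: RasterGrid | None = None, seed: int = 0,
                     id_prefix: str = "occ", range_label: str = "native") -> OccurrenceSet:
    """Draw presence records with probability proportional to suitability x bias.

    Cells are drawn with replacement (several records may share a cell
    before grid-deduplication, as in real compilations) and positions are
    jittered uniformly within the cell.
    """
    valid = ~suitability.nodata_mask
    p = np.where(valid, suitability.values, 0.0)
    if bias is not None:
        if not bias.same_frame(suitability):
            raise ValueError("bias raster must share the suitability grid frame")
        p = p * np.where(valid & ~bias.nodata_mask, bias.values, 0.0)
    total = p.sum()
    if total <= 0:
        raise ValueError("suitability (x bias) is zero everywhere")
    rng = np.random.default_rng(seed)
    flat = rng.choice(p.size, size=n, replace=True, p=(p / total).ravel())
    rows, cols = np.unravel_index(flat, p.shape)
    jx = rng.random(n) - 0.5
    jy = rng.random(n) - 0.5
    x = suitability.x_origin + (cols + 0.5 + jx) * suitability.cell_size
    y = suitability.y_origin - (rows + 0.5 + jy) * suitability.cell_size
    records = pd.DataFrame({
        "id": [f"{id_prefix}-{i:05d}" for i in range(n)],
        "species": "virtualis", "longitude": x, "latitude": y,
        "range_label": range_label, "source": "synthetic",
    })[REQUIRED_COLUMNS]
    occ = OccurrenceSet(records)
    occ.log_step("sample_presences", n, n, seed=seed, range_label=range_label)
    return occ


def sampling_bias_field(config: VirtualSpeciesConfig, frame: RasterGrid) -> RasterGrid:
    """East-west exponential sampling-effort gradient, max 1."""
    xx = np.linspace(0.0, 1.0, frame.n_cols)[None, :] * np.ones((frame.n_rows, 1))
    b = np.exp(config.bias_strength * xx)
    return frame.copy_with(b / b.max())


@dataclass
class RangeData:
    """Everything generated for one range (landscape + species truth)."""

    monthly: _climate.MonthlyClimate
    stack: RasterStack
    mask: RasterGrid
    suitability: RasterGrid
    bias: RasterGrid
    occurrences: OccurrenceSet
    mu: dict
    env_table: pd.DataFrame = field(repr=False, default=None)


@dataclass
class SyntheticStudy:
    """Paired native/invaded study with its full truth record."""

    config: VirtualSpeciesConfig
    native: RangeData
    invaded: RangeData
    sigma: dict
    shift_direction: dict             # unit vector in standardized variable space
    delta: float
    pooled_mean: dict
    pooled_sd: dict

    @property
    def truth(self) -> dict:
        return {
            "delta": self.delta,
            "sigma": self.sigma,
            "mu_native": self.native.mu,
            "mu_invaded": self.invaded.mu,
            "shift_direction": self.shift_direction,
            "pooled_mean": self.pooled_mean,
            "pooled_sd": self.pooled_sd,
        }


def generate_invasion_study(config: VirtualSpeciesConfig) -> SyntheticStudy:
    """Generate the full paired-range study.

    The two landscapes are independent draws of the same climate process.
    Optima are placed at -delta/2 and +delta/2 along the first principal
    axis of the pooled standardized background climate, so the true niche
    separation is ``delta`` pooled-background SD units.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    nat_monthly, nat_mask = generate_landscape(config, seed=seeds[0])
    inv_monthly, inv_mask = generate_landscape(config, seed=seeds[1])
    nat_stack = _climate.derive_bioclim(nat_monthly)
    inv_stack = _climate.derive_bioclim(inv_monthly)
    variables = list(config.variables)

    nat_env = pd.DataFrame(dict(zip(variables, nat_stack.table(variables).T)))
    inv_env = pd.DataFrame(dict(zip(variables, inv_stack.table(variables).T)))
    pooled = np.vstack([nat_env.to_numpy(float), inv_env.to_numpy(float)])
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd = np.maximum(sd, 1e-12)
    z = (pooled - mean) / sd
    # first principal axis of the pooled standardized background
    _, _, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    u = vt[0]
    u = u / np.linalg.norm(u)

    mu_nat = {v: mean[i] + (-config.delta / 2.0) * u[i] * sd[i] for i, v in enumerate(variables)}
    mu_inv = {v: mean[i] + (+config.delta / 2.0) * u[i] * sd[i] for i, v in enumerate(variables)}
    sigma = {v: config.niche_breadth * sd[i] for i, v in enumerate(variables)}

    nat_suit = true_suitability(nat_stack, variables, mu_nat, sigma, config.suit_intercept)
    inv_suit = true_suitability(inv_stack, variables, mu_inv, sigma, config.suit_intercept)
    nat_bias = sampling_bias_field(config, nat_suit)
    inv_bias = sampling_bias_field(config, inv_suit)
    nat_occ = sample_presences(nat_suit, config.n_presences, bias=nat_bias,
                               seed=seeds[2], id_prefix="nat", range_label="native")
    inv_occ = sample_presences(inv_suit, config.n_presences, bias=inv_bias,
                               seed=seeds[3], id_prefix="inv", range_label="invasive_conus")

    return SyntheticStudy(
        config=config,
        native=RangeData(nat_monthly, nat_stack, nat_mask, nat_suit, nat_bias,
                         nat_occ, mu_nat, env_table=nat_env),
        invaded=RangeData(inv_monthly, inv_stack, inv_mask, inv_suit, inv_bias,
                          inv_occ, mu_inv, env_table=inv_env),
        sigma=sigma,
        shift_direction=dict(zip(variables, u.tolist())),
        delta=config.delta,
        pooled_mean=dict(zip(variables, mean.tolist())),
        pooled_sd=dict(zip(variables, sd.tolist())),
    )


def morans_i(values: np.ndarray) -> float:
    """Moran's I with rook adjacency — spatial-autocorrelation diagnostic."""
    z = values - values.mean()
    num = (z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum()
    n_pairs = z[:, :-1].size + z[:-1, :].size
    return float((num / n_pairs) / (z**2).mean())
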