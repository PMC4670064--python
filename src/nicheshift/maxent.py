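"""Presence-background maximum-entropy niche model.

The model estimates a Gibbs distribution over background cells,

    q(x) = w(x) exp(eta(x)) / Z_w,     eta(x) = sum_j lambda_j f_j(x),

by maximizing the penalized log-likelihood of the presence sample

    (1/m) sum_presences eta(x) - log Z_w - beta * sum_j s_j |lambda_j|,

where f_j are feature expansions (linear, quadratic, product, hinge) of
min-max-scaled predictors, w are optional background weights, and s_j are
per-feature regularization scales (class base value interpolated by
presence sample size, times the feature's background SD over sqrt(m) —
the convention of the reference MaxEnt software, tabulated in
``REG_TABLES`` below).  beta is the global regularization multiplier.

Fitting is proximal-gradient (monotone FISTA with backtracking and
adaptive restart): the smooth part's gradient is the gap between the
background-expected and presence-mean feature vectors, and the L1 penalty
enters through the soft-threshold proximal step.  At beta = 0 with linear
features the optimum therefore satisfies exact moment matching:
E_q[f] = presence mean of f.

The logistic output s = e^H q~ / (1 + e^H q~) (q~ the unweighted raw
probability, H its entropy over the training background) maps relative
suitability to (0,1) with a null model scoring 0.5 everywhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterGrid, RasterStack

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")

# Regularization base values by feature class, interpolated in the presence
# sample size m (reference MaxEnt defaults).
REG_TABLES = {
    "linear": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "product": ([0, 10, 17, 30, 100], [2.6, 1.6, 1.0, 1.0, 0.05]),
    "hinge": ([0, 1], [0.5, 0.5]),
}


def class_reg_base(kind: str, m: int) -> float:
    xs, ys = REG_TABLES[kind]
    return float(np.interp(m, xs, ys))


@dataclass
class FeatureSpec:
    """One feature: its class, source variable(s), and hinge knot/direction."""

    kind: str                       # linear | quadratic | product | hinge
    variables: tuple[str, ...]
    knot: float | None = None       # hinge knot in scaled [0,1] units
    direction: str | None = None    # "fwd": max(0,(x-k)/(1-k)); "rev": max(0,(k-x)/k)

    def label(self) -> str:
        if self.kind == "hinge":
            return f"hinge_{self.direction}({self.variables[0]}@{self.knot:.3f})"
        if self.kind == "product":
            return f"{self.variables[0]}*{self.variables[1]}"
        if self.kind == "quadratic":
            return f"{self.variables[0]}^2"
        return self.variables[0]


class FeatureExpander:
    """Feature expansion bound to background-derived min-max scaling bounds."""

    def __init__(self, specs: list[FeatureSpec], bounds: dict[str, tuple[float, float]]):
        self.specs = specs
        self.bounds = bounds    # raw-variable (min, max) over the background

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for s in self.specs:
            for v in s.variables:
                if v not in seen:
                    seen.append(v)
        return seen

    def scale(self, env: pd.DataFrame, clamp: bool = False) -> dict[str, np.ndarray]:
        out = {}
        for v, (lo, hi) in self.bounds.items():
            if v not in env.columns:
                raise KeyError(f"environment table missing model variable {v!r}")
            x = env[v].to_numpy(dtype=float)
            z = (x - lo) / (hi - lo)
            out[v] = np.clip(z, 0.0, 1.0) if clamp else z
        return out

    def transform(self, env: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        z = self.scale(env, clamp=clamp)
        cols = []
        for s in self.specs:
            if s.kind == "linear":
                cols.append(z[s.variables[0]])
            elif s.kind == "quadratic":
                cols.append(z[s.variables[0]] ** 2)
            elif s.kind == "product":
                cols.append(z[s.variables[0]] * z[s.variables[1]])
            else:
                x, k = z[s.variables[0]], s.knot
                if s.direction == "fwd":
                    cols.append(np.clip((x - k) / (1.0 - k), 0.0, None))
                else:
                    cols.append(np.clip((k - x) / k, 0.0, None))
        return np.column_stack(cols) if cols else np.empty((len(env), 0))


def build_feature_matrix(
    env: pd.DataFrame,
    classes=("linear", "quadratic", "hinge"),
    n_hinge_knots: int = 50,
) -> tuple[np.ndarray, FeatureExpander]:
    """Build the background design matrix and its bound feature expander.

    ``env`` must be the *background* environment table: scaling bounds and
    constant-column screening are defined on it.  Constant columns are
    dropped with a warning; requesting product features with a single
    variable yields none (warning).
    """
    unknown = set(classes) - set(FEATURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    bounds = {}
    for v in env.columns:
        lo, hi = float(env[v].min()), float(env[v].max())
        if hi <= lo:
            warnings.warn(f"background column {v!r} is constant; dropped from features")
            continue
        bounds[v] = (lo, hi)
    variables = list(bounds)
    specs: list[FeatureSpec] = []
    if "linear" in classes:
        specs += [FeatureSpec("linear", (v,)) for v in variables]
    if "quadratic" in classes:
        specs += [FeatureSpec("quadratic", (v,)) for v in variables]
    if "product" in classes:
        if len(variables) < 2:
            warnings.warn("product features need >= 2 variables; none built")
        else:
            specs += [
                FeatureSpec("product", (variables[i], variables[j]))
                for i in range(len(variables))
                for j in range(i + 1, len(variables))
            ]
    if "hinge" in classes:
        knots = (np.arange(1, n_hinge_knots + 1)) / (n_hinge_knots + 1)
        for v in variables:
            specs += [FeatureSpec("hinge", (v,), knot=float(k), direction="fwd") for k in knots]
            specs += [FeatureSpec("hinge", (v,), knot=float(k), direction="rev") for k in knots]
    expander = FeatureExpander(specs, bounds)
    return expander.transform(env), expander


def feature_reg_scales(background_dm: np.ndarray, specs: list[FeatureSpec],
                       m_presences: int) -> np.ndarray:
    """Per-feature penalty scales s_j: class base(m) * sd_j(background) / sqrt(m)."""
    sd = background_dm.std(axis=0)
    sd = np.maximum(sd, 1e-12)
    base = np.array([class_reg_base(s.kind, m_presences) for s in specs])
    return base * sd / np.sqrt(max(m_presences, 1))


class NonConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: np.ndarray):
        super().__init__(message)
        self.trace = trace


@dataclass
class MaxentModel:
    """Fitted model: features, coefficients, normalizers and entropy."""

    expander: FeatureExpander
    lam: np.ndarray                     # coefficient per feature
    beta: float
    reg_scales: np.ndarray
    log_z_weighted: float               # log Z_w over training background
    log_z_unweighted: float             # log sum_bg e^eta (uniform weights)
    entropy: float                      # H of the unweighted raw distribution
    n_background: int
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.lam) > 1e-8))

    def eta(self, env: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        return self.expander.transform(env, clamp=clamp) @ self.lam

    # ---- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "bounds": self.expander.bounds,
            "features": [
                {"kind": s.kind, "variables": list(s.variables),
                 "knot": s.knot, "direction": s.direction}
                for s in self.expander.specs
            ],
            "lam": self.lam.tolist(),
            "beta": self.beta,
            "reg_scales": self.reg_scales.tolist(),
            "log_z_weighted": self.log_z_weighted,
            "log_z_unweighted": self.log_z_unweighted,
            "entropy": self.entropy,
            "n_background": self.n_background,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        d = json.loads(text)
        specs = [FeatureSpec(f["kind"], tuple(f["variables"]), f["knot"], f["direction"])
                 for f in d["features"]]
        bounds = {k: tuple(v) for k, v in d["bounds"].items()}
        return cls(
            expander=FeatureExpander(specs, bounds),
            lam=np.asarray(d["lam"], float),
            beta=d["beta"],
            reg_scales=np.asarray(d["reg_scales"], float),
            log_z_weighted=d["log_z_weighted"],
            log_z_unweighted=d["log_z_unweighted"],
            entropy=d["entropy"],
            n_background=d["n_background"],
        )


def _soft_threshold(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def fit_maxent(
    presence_dm: np.ndarray,
    background_dm: np.ndarray,
    background_weights: np.ndarray | None = None,
    beta: float = 1.0,
    expander: FeatureExpander | None = None,
    reg_scales: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 5000,
) -> MaxentModel:
    """Fit the penalized maximum-entropy model by monotone FISTA.

    ``presence_dm`` / ``background_dm`` are design matrices from the same
    :class:`FeatureExpander` (pass it to get a usable model object back).
    Convergence: absolute objective change below ``tol``; exceeding
    ``max_iter`` raises :class:`NonConvergenceError` with the trace.
    """
    P = np.asarray(presence_dm, float)
    B = np.asarray(background_dm, float)
    m, p = P.shape
    if m < 2:
        raise ValueError("need at least 2 presence rows")
    if B.shape[0] < m:
        raise ValueError("background must be at least as large as the presence sample")
    w = np.ones(B.shape[0]) if background_weights is None else np.asarray(background_weights, float)
    w = w / w.sum()
    logw = np.log(w)
    if reg_scales is None:
        if expander is None:
            reg_scales = B.std(axis=0) / np.sqrt(m)
            reg_scales = np.maximum(reg_scales, 1e-12)
        else:
            reg_scales = feature_reg_scales(B, expander.specs, m)
    pen = beta * np.asarray(reg_scales, float)
    pbar = P.mean(axis=0)

    def smooth(lam):
        """log Z_w - presence mean eta, plus gradient."""
        a = logw + B @ lam
        amax = a.max()
        e = np.exp(a - amax)
        z = e.sum()
        logz = amax + np.log(z)
        q = e / z
        return logz - pbar @ lam, B.T @ q - pbar

    def objective(lam, f_smooth=None):
        if f_smooth is None:
            f_smooth = smooth(lam)[0]
        return f_smooth + pen @ np.abs(lam)

    lam = np.zeros(p)
    f_lam, g_lam = smooth(lam)
    F = objective(lam, f_lam)
    trace = [F]
    z = lam.copy()
    t_mom = 1.0
    L = 1.0
    converged = False
    for _ in range(max_iter):
        # momentum point (falls back to plain proximal step if non-monotone)
        y = z
        f_y, g_y = smooth(y)
        while True:
            cand = _soft_threshold(y - g_y / L, pen / L)
            f_c = smooth(cand)[0]
            d = cand - y
            if f_c <= f_y + g_y @ d + 0.5 * L * (d @ d) + 1e-12:
                break
            L *= 2.0
        F_c = objective(cand, f_c)
        if F_c > F:                       # restart from the best iterate
            y = lam
            f_y, g_y = smooth(y)
            while True:
                cand = _soft_threshold(y - g_y / L, pen / L)
                f_c = smooth(cand)[0]
                d = cand - y
                if f_c <= f_y + g_y @ d + 0.5 * L * (d @ d) + 1e-12:
                    break
                L *= 2.0
            F_c = objective(cand, f_c)
            t_mom = 1.0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        z = cand + ((t_mom - 1.0) / t_next) * (cand - lam)
        t_mom = t_next
        delta = F - F_c
        if F_c <= F:
            lam, F = cand, F_c
        trace.append(F)
        L = max(L / 2.0, 1e-6)            # gentle step-size recovery
        if 0 <= delta < tol:
            converged = True
            break
    if not converged:
        raise NonConvergenceError(
            f"maxent fit did not converge in {max_iter} iterations "
            f"(last objective {trace[-1]:.10g})", np.asarray(trace))

    eta_bg = B @ lam
    aw = logw + eta_bg
    log_zw = float(aw.max() + np.log(np.exp(aw - aw.max()).sum()))
    au = eta_bg
    log_zu = float(au.max() + np.log(np.exp(au - au.max()).sum()))
    q_u = np.exp(au - log_zu)
    entropy = float(-(q_u * np.log(np.maximum(q_u, 1e-300))).sum())
    if expander is None:
        expander = FeatureExpander([], {})
    return MaxentModel(
        expander=expander, lam=lam, beta=beta, reg_scales=np.asarray(reg_scales, float),
        log_z_weighted=log_zw, log_z_unweighted=log_zu, entropy=entropy,
        n_background=B.shape[0], objective_trace=np.asarray(trace),
    )


# ---- prediction -----------------------------------------------------------


def raw_probabilities(model: MaxentModel, dm: np.ndarray,
                      weights: np.ndarray | None = None,
                      renormalize: bool = False) -> np.ndarray:
    """Raw (relative occurrence) probabilities q = w e^eta / Z_w.

    Z_w is the training-background normalizer, so over the training
    background the values sum to 1.  With ``renormalize`` the values are
    rescaled to sum to 1 over the given rows (used for likelihoods over a
    full landscape).
    """
    dm = np.asarray(dm, float)
    eta = dm @ model.lam
    w = np.ones(dm.shape[0]) if weights is None else np.asarray(weights, float)
    logq = eta - model.log_z_weighted + np.log(w / w.sum())
    q = np.exp(logq)
    if renormalize:
        q = q / q.sum()
    return q


def logistic_suitability(model: MaxentModel, env: pd.DataFrame,
                         clamp: bool = False) -> np.ndarray:
    """Logistic suitability in (0,1); rank-preserving transform of q~."""
    eta = model.eta(env, clamp=clamp)
    g = model.entropy + eta - model.log_z_unweighted   # log(e^H q~)
    return 1.0 / (1.0 + np.exp(-g))


def predict_raster(model: MaxentModel, stack: RasterStack, clamp: bool = True) -> RasterGrid:
    """Apply the model across a raster stack; nodata propagates.

    With ``clamp`` (default) predictor values beyond the training bounds
    are held at the bounds — the standard projection safeguard.
    """
    for v in model.expander.variables:
        if v not in stack:
            raise KeyError(f"raster stack missing model variable {v!r}")
    mask = stack.combined_mask()
    env = pd.DataFrame({v: stack[v].values[~mask] for v in model.expander.bounds})
    s = logistic_suitability(model, env, clamp=clamp)
    out = np.full(stack.frame.shape, np.nan)
    out[~mask] = s
    return stack.frame.copy_with(out, mask.copy())


# ---- diagnostics ----------------------------------------------------------


def training_gain(model: MaxentModel, presence_env: pd.DataFrame,
                  background_env: pd.DataFrame) -> float:
    """Mean presence log-probability relative to a uniform null (nats)."""
    eta_p = model.eta(presence_env)
    eta_b = model.eta(background_env)
    a = eta_b
    log_z = a.max() + np.log(np.exp(a - a.max()).sum())
    return float(eta_p.mean() - log_z + np.log(len(background_env)))


def variable_importance(
    model: MaxentModel,
    presence_env: pd.DataFrame,
    background_env: pd.DataFrame,
    seed: int = 0,
    n_permutations: int = 3,
    jackknife: bool = False,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Percent contribution via permutation importance (+ optional jackknife).

    For each variable, its raw values are permuted jointly across presence
    and background rows and the drop in training gain (coefficients fixed)
    is recorded; drops are clipped at zero and normalized to sum 100.
    With ``jackknife``, models are refit with only / without each variable
    and their training gains reported.
    """
    rng = np.random.default_rng(seed)
    variables = model.expander.variables
    base_gain = training_gain(model, presence_env, background_env)
    n_p = len(presence_env)
    drops = {}
    for v in variables:
        d = []
        for _ in range(n_permutations):
            combined = np.concatenate([
                presence_env[v].to_numpy(float), background_env[v].to_numpy(float)])
            rng.shuffle(combined)
            pe = presence_env.copy()
            be = background_env.copy()
            pe[v] = combined[:n_p]
            be[v] = combined[n_p:]
            d.append(base_gain - training_gain(model, pe, be))
        drops[v] = max(np.mean(d), 0.0)
    total = sum(drops.values())
    if total == 0:
        contrib = {v: 100.0 / len(variables) for v in variables}
    else:
        contrib = {v: 100.0 * drops[v] / total for v in variables}
    out = pd.DataFrame({"percent_contribution": pd.Series(contrib)})

    if jackknife:
        fit_kwargs = fit_kwargs or {}
        classes = tuple(sorted({s.kind for s in model.expander.specs}))
        only, without = {}, {}
        for v in variables:
            for label, keep in (("gain_only", [v]), ("gain_without", [u for u in variables if u != v])):
                if not keep:
                    continue
                bdm, exp_v = build_feature_matrix(background_env[keep], classes=classes,
                                                  n_hinge_knots=fit_kwargs.get("n_hinge_knots", 10))
                pdm = exp_v.transform(presence_env[keep])
                sub = fit_maxent(pdm, bdm, beta=model.beta, expander=exp_v,
                                 tol=fit_kwargs.get("tol", 1e-6),
                                 max_iter=fit_kwargs.get("max_iter", 5000))
                gain = training_gain(sub, presence_env[keep], background_env[keep])
                (only if label == "gain_only" else without)[v] = gain
        out["gain_only"] = pd.Series(only)
        out["gain_without"] = pd.Series(without)
    return out.loc[variables]


def response_curve(model: MaxentModel, variable: str,
                   background_env: pd.DataFrame, n_points: int = 100):
    """Suitability vs one variable (others at background means).

    Returns (grid values, suitability, interior mode count), the mode count
    being the number of strict interior local maxima — the screening
    statistic for biologically implausible (jagged/multimodal) responses.
    """
    lo, hi = model.expander.bounds[variable]
    xs = np.linspace(lo, hi, n_points)
    env = pd.DataFrame({
        v: np.full(n_points, background_env[v].to_numpy(float).mean())
        for v in model.expander.bounds
    })
    env[variable] = xs
    s = logistic_suitability(model, env)
    modes = count_interior_modes(s)
    return xs, s, modes


def count_interior_modes(y: np.ndarray) -> int:
    """Strict interior local maxima of a sampled curve."""
    y = np.asarray(y, float)
    if y.size < 3:
        return 0
    left = y[1:-1] > y[:-2]
    right = y[1:-1] > y[2:]
    return int(np.sum(left & right))


# ---- model selection ------------------------------------------------------


@dataclass
class ModelCandidate:
    """One feature-class/beta setting with its fit and selection statistics."""

    name: str
    classes: tuple[str, ...]
    beta: float
    model: MaxentModel
    log_likelihood: float = np.nan
    k: int = 0
    aicc: float = np.nan
    max_modes: int = 0
    rank: int | None = None
    excluded: str | None = None


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion; undefined for k >= n-1."""
    if k >= n - 1:
        return np.nan
    return 2 * k - 2 * log_likelihood + 2 * k * (k + 1) / (n - k - 1)


def aicc_rank(
    candidates: list[ModelCandidate],
    presence_env: pd.DataFrame,
    landscape_env: pd.DataFrame,
    max_interior_modes: int = 3,
) -> list[ModelCandidate]:
    """Rank candidates by AICc of the landscape-renormalized raw distribution.

    ln L = sum over presences of ln q-hat, with q-hat the raw distribution
    renormalized over the full landscape; k counts nonzero coefficients.
    Candidates with undefined AICc (k >= n-1) or with any response curve
    showing more than ``max_interior_modes`` interior maxima are excluded
    from the ranking.  Returns candidates sorted: ranked ones first by
    ascending AICc.
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    n = len(presence_env)
    for c in candidates:
        eta_land = c.model.eta(landscape_env, clamp=True)
        a = eta_land
        log_z = a.max() + np.log(np.exp(a - a.max()).sum())
        eta_p = c.model.eta(presence_env, clamp=True)
        c.log_likelihood = float((eta_p - log_z).sum())
        c.k = c.model.n_nonzero
        c.aicc = aicc(c.log_likelihood, c.k, n)
        c.max_modes = max(
            (response_curve(c.model, v, landscape_env)[2] for v in c.model.expander.variables),
            default=0,
        )
        if not np.isfinite(c.aicc):
            c.excluded = f"AICc undefined (k={c.k}, n={n})"
        elif c.max_modes > max_interior_modes:
            c.excluded = f"response curves too complex ({c.max_modes} interior modes)"
    ranked = sorted([c for c in candidates if c.excluded is None], key=lambda c: c.aicc)
    if not ranked:
        raise ValueError("all candidates excluded from AICc ranking")
    for i, c in enumerate(ranked):
        c.rank = i + 1
    return ranked + [c for c in candidates if c.excluded is not None]
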