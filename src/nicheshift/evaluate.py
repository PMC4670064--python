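"""Model performance: cross-validated AUC, partial-ROC ratio, omission rates.

Presence-background evaluation treats background points as the "negative"
class for ROC purposes; AUC is therefore an index of discrimination
between presence sites and available environment, not true
presence/absence accuracy.  The partial-ROC ratio confines the comparison
to the high-sensitivity region relevant for presence-only models: the
model's partial AUC over sensitivities >= 1 - E is divided by the
random-expectation partial AUC over the same region, so a ratio above 1
indicates better-than-random performance (2.0 for a perfect model at
E = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .raster import RasterGrid


def kfold_cv(n_presences: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random fold assignment (0..k-1) with fold sizes within one of each other."""
    if n_presences < k:
        raise ValueError(f"need at least k={k} presences, got {n_presences}")
    rng = np.random.default_rng(seed)
    folds = np.arange(n_presences) % k
    rng.shuffle(folds)
    return folds


def roc_auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count half."""
    sp = np.asarray(scores_presence, float)
    sb = np.asarray(scores_background, float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be nonempty")
    pooled = np.concatenate([sp, sb])
    if np.all(pooled == pooled[0]):
        warnings.warn("constant scores: AUC undefined, returning 0.5")
        return 0.5
    ranks = stats.rankdata(pooled)
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


def omission_thresholds(train_scores: np.ndarray, rates=(0.0, 0.10)) -> dict[float, float]:
    """Suitability thresholds at given training omission rates.

    The threshold at rate r is the r-quantile of training presence scores
    (lower interpolation; r = 0 gives the minimum training presence).
    """
    s = np.asarray(train_scores, float)
    if s.size == 0:
        raise ValueError("training scores are empty")
    return {float(r): float(np.quantile(s, r, method="lower")) for r in rates}


def omission_sensitivity(test_scores: np.ndarray, threshold: float) -> float:
    """Fraction of test presences at or above the threshold (sensitivity)."""
    s = np.asarray(test_scores, float)
    if s.size == 0:
        raise ValueError("test scores are empty; sensitivity undefined")
    return float(np.mean(s >= threshold))


@dataclass
class PartialRocResult:
    ratio_mean: float
    ratio_sd: float
    p_value: float          # fraction of bootstrap ratios <= 1
    ratios: np.ndarray = field(repr=False)
    expected_omission: float = 0.0


def _pauc_ratio_once(cell_scores_sorted: np.ndarray, test_scores: np.ndarray,
                     E: float) -> float:
    """Partial-AUC ratio for one set of test points.

    x-axis: fraction of landscape predicted present at each threshold;
    y-axis: test sensitivity.  Integration is restricted to the curve
    segment with sensitivity >= 1 - E; the random expectation is the
    diagonal y = x over the same x-range.
    """
    n_cells = cell_scores_sorted.size
    thresholds = np.unique(test_scores)
    # fraction of cells with score >= t  (cell_scores_sorted ascending)
    area = 1.0 - np.searchsorted(cell_scores_sorted, thresholds, side="left") / n_cells
    sens = (test_scores[None, :] >= thresholds[:, None]).mean(axis=1)
    # assemble the ROC-like curve in increasing area order, with endpoints
    x = np.concatenate([[0.0], area[::-1], [1.0]])
    y = np.concatenate([[0.0], sens[::-1], [1.0]])
    keep = y >= (1.0 - E) - 1e-12
    if keep.sum() < 1:
        return np.nan
    x_k, y_k = x[keep], y[keep]
    if x_k[0] > 0.0 and not keep[0]:
        # interpolate the entry point where sensitivity crosses 1-E
        i = np.argmax(keep)
        x0, x1 = x[i - 1], x[i]
        y0, y1 = y[i - 1], y[i]
        t = 0.0 if y1 == y0 else ((1.0 - E) - y0) / (y1 - y0)
        x_k = np.concatenate([[x0 + t * (x1 - x0)], x_k])
        y_k = np.concatenate([[1.0 - E], y_k])
    pauc_model = np.trapezoid(y_k, x_k)
    pauc_random = 0.5 * (x_k[-1] ** 2 - x_k[0] ** 2)
    if pauc_random <= 0:
        return np.nan
    return float(pauc_model / pauc_random)


def partial_roc_ratio(
    pred_raster: RasterGrid | np.ndarray,
    test_scores: np.ndarray,
    E: float = 0.0,
    boot_prop: float = 0.5,
    reps: int = 1000,
    seed: int = 0,
) -> PartialRocResult:
    """Bootstrap partial-ROC ratio of a prediction against test presences.

    Each rep resamples ``boot_prop`` of the test points with replacement
    and recomputes the ratio; p is the fraction of reps with ratio <= 1
    (better-than-random has ratio > 1).
    """
    if E >= 1:
        raise ValueError("expected omission E must be < 1")
    if isinstance(pred_raster, RasterGrid):
        cells = pred_raster.valid_values()
    else:
        cells = np.asarray(pred_raster, float).ravel()
        cells = cells[np.isfinite(cells)]
    cells = np.sort(cells)
    test = np.asarray(test_scores, float)
    test = test[np.isfinite(test)]
    if test.size == 0:
        raise ValueError("no valid test points")
    rng = np.random.default_rng(seed)
    n_boot = max(1, int(round(boot_prop * test.size)))
    ratios = np.empty(reps)
    for i in range(reps):
        sample = test[rng.integers(0, test.size, n_boot)]
        ratios[i] = _pauc_ratio_once(cells, sample, E)
    ok = np.isfinite(ratios)
    if not ok.any():
        raise ValueError("partial ROC undefined for every bootstrap rep")
    r = ratios[ok]
    return PartialRocResult(
        ratio_mean=float(r.mean()), ratio_sd=float(r.std(ddof=1)) if r.size > 1 else 0.0,
        p_value=float(np.mean(r <= 1.0)), ratios=ratios, expected_omission=E,
    )


@dataclass
class EvalResult:
    """Cross-validation and threshold metrics for one fitted model setting."""

    auc_cv_mean: float
    auc_cv_sd: float
    fold_aucs: list[float]
    pauc_ratio_mean: float
    pauc_ratio_sd: float
    pauc_p: float
    thresholds: dict[float, float]              # omission rate -> threshold
    test_sensitivity: dict[float, float]        # omission rate -> sensitivity
    test_omission: dict[float, float]           # omission rate -> omission (1 - sens)
    folds: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "auc_cv_mean": self.auc_cv_mean,
            "auc_cv_sd": self.auc_cv_sd,
            "fold_aucs": list(map(float, self.fold_aucs)),
            "pauc_ratio_mean": self.pauc_ratio_mean,
            "pauc_ratio_sd": self.pauc_ratio_sd,
            "pauc_p": self.pauc_p,
            "thresholds": {str(k): v for k, v in self.thresholds.items()},
            "test_sensitivity": {str(k): v for k, v in self.test_sensitivity.items()},
            "test_omission": {str(k): v for k, v in self.test_omission.items()},
            "seed": self.seed,
        }
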