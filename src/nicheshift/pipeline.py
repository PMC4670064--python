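"""End-to-end analysis pipeline and structured report.

Runs the full invasion-niche analysis from one config: synthetic study
generation (or supplied files), occurrence filtering, collinearity
screening of the 20-variable climate set, candidate maxent fitting with
AICc ranking, cross-validated evaluation, PCA-env niche comparison, and
invasion-stage classification — emitting a machine-readable JSON report
plus a human-readable summary.

One top-level seed fans out to per-stage seeds through a stable CRC32
hash of "<seed>:<stage>", so any stage can be rerun independently and the
whole report is reproducible: the same config always yields the same
report hash.
"""

from __future__ import annotations

import hashlib
import json
import os
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .climate import BIOCLIM_NAMES, correlation_matrix, extract_env_values, prune_collinear
from .evaluate import (EvalResult, kfold_cv, omission_sensitivity,
                       omission_thresholds, partial_roc_ratio, roc_auc)
from .maxent import (ModelCandidate, aicc_rank, build_feature_matrix, fit_maxent,
                     logistic_suitability, predict_raster, variable_importance)
from .occurrences import OccurrenceSet, bias_surface, dedupe_to_grid, sample_background, spatial_thin
from .overlap import compare_niches
from .stages import classify_stage, classify_stage_raster
from .synth import SyntheticStudy, VirtualSpeciesConfig, generate_invasion_study

#: keep-priority order for the collinearity screen: the variables most
#: informative for thermally limited invasive insects first.
DEFAULT_VARIABLE_PRIORITY = [
    "bio2", "bio3", "bio4", "bio8", "bio15", "bio16", "bio17", "degdays10",
] + [n for n in BIOCLIM_NAMES if n not in
     {"bio2", "bio3", "bio4", "bio8", "bio15", "bio16", "bio17", "degdays10"}]

DEFAULT_CANDIDATES = [
    {"classes": ["linear", "quadratic", "hinge"], "beta": 1.5},
    {"classes": ["linear", "quadratic", "product"], "beta": 2.5},
    {"classes": ["linear", "quadratic", "product", "hinge"], "beta": 2.5},
]


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "nicheshift_out"
    study: dict = field(default_factory=dict)       # VirtualSpeciesConfig overrides
    thin_min_dist_km: float = 1.0
    bias_bandwidth_km: float | None = None          # default: 2 x thinning distance
    background_mode: str = "selection"              # selection | weights | none
    n_background: int = 10_000
    corr_threshold: float = 0.80
    variable_priority: list = field(default_factory=lambda: list(DEFAULT_VARIABLE_PRIORITY))
    candidates: list = field(default_factory=lambda: [dict(c) for c in DEFAULT_CANDIDATES])
    n_hinge_knots: int = 10
    cv_folds: int = 10
    pauc_expected_omission: float = 0.0
    pauc_reps: int = 1000
    pauc_boot_prop: float = 0.5
    overlap_reps: int = 100
    overlap_grid_R: int = 100
    stage_tau: float = 0.5
    max_interior_modes: int = 3

    def __post_init__(self):
        if self.background_mode not in {"selection", "weights", "none"}:
            raise ValueError(f"invalid background_mode {self.background_mode!r}")
        if self.bias_bandwidth_km is None:
            self.bias_bandwidth_km = 2.0 * self.thin_min_dist_km

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Derived per-stage seed: stable across runs and platforms."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, provenance: list, cause: Exception):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.provenance = provenance


@dataclass
class AnalysisReport:
    """Full machine-readable pipeline output."""

    config: dict
    config_hash: str
    version: str
    provenance: list
    performance: dict                 # per model role: Table-1-style block
    contributions: dict               # per model role: percent contribution
    overlaps: list                    # OverlapResult dicts per contrast
    stage_summary: dict

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "config": self.config,
            "provenance": self.provenance,
            "performance": self.performance,
            "contributions": self.contributions,
            "overlaps": self.overlaps,
            "stage_summary": self.stage_summary,
        }

    def canonical_json(self) -> str:
        return json.dumps(_roundtrip(self.to_dict()), sort_keys=True, indent=1)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _roundtrip(obj):
    """Coerce numpy scalars/arrays to plain JSON types."""
    if isinstance(obj, dict):
        return {str(k): _roundtrip(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_roundtrip(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_roundtrip(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _prep_range(occ: OccurrenceSet, range_data, cfg: PipelineConfig, label: str):
    """Dedupe, thin, bias-surface and background-sample one range."""
    grid = range_data.stack.frame
    occ = dedupe_to_grid(occ, grid)
    occ = spatial_thin(occ, cfg.thin_min_dist_km,
                       seed=stage_seed(cfg.seed, f"thin:{label}"), crs_tag=grid.crs_tag)
    bias = bias_surface(occ, grid, cfg.bias_bandwidth_km)
    bg_bias = bias if cfg.background_mode == "selection" else None
    bg = sample_background(range_data.mask, n=cfg.n_background, bias=bg_bias,
                           seed=stage_seed(cfg.seed, f"background:{label}"))
    ex_occ = extract_env_values(occ.records["id"], occ.records["longitude"],
                                occ.records["latitude"], range_data.stack)
    bg_env = pd.DataFrame(
        {n: range_data.stack[n].values[bg.rows, bg.cols] for n in range_data.stack.names})
    bg_weights = None
    if cfg.background_mode == "weights":
        bg_weights = bias.values[bg.rows, bg.cols]
    return occ, ex_occ.table, bg, bg_env, bg_weights


def _fit_role(role: str, pres_env: pd.DataFrame, bg_env: pd.DataFrame,
              bg_weights, variables: list, cfg: PipelineConfig):
    """Fit the candidate grid for one model role and rank by AICc."""
    candidates = []
    for spec in cfg.candidates:
        classes = tuple(spec["classes"])
        beta = float(spec["beta"])
        bdm, expander = build_feature_matrix(bg_env[variables], classes=classes,
                                             n_hinge_knots=cfg.n_hinge_knots)
        pdm = expander.transform(pres_env[variables])
        model = fit_maxent(pdm, bdm, background_weights=bg_weights, beta=beta,
                           expander=expander)
        name = "".join(c[0].upper() for c in classes) + f"_b{beta:g}"
        candidates.append(ModelCandidate(name=name, classes=classes, beta=beta, model=model))
    ranked = aicc_rank(candidates, pres_env[variables], bg_env[variables],
                       max_interior_modes=cfg.max_interior_modes)
    return ranked


def _evaluate_role(role: str, best: ModelCandidate, pres_env: pd.DataFrame,
                   bg_env: pd.DataFrame, bg_weights, variables: list,
                   pred_raster, cfg: PipelineConfig) -> EvalResult:
    seed = stage_seed(cfg.seed, f"eval:{role}")
    n = len(pres_env)
    folds = kfold_cv(n, k=cfg.cv_folds, seed=seed)
    bg_scores = logistic_suitability(best.model, bg_env[variables])
    fold_aucs = []
    heldout_scores = np.empty(n)
    for f in range(cfg.cv_folds):
        train = folds != f
        bdm, expander = build_feature_matrix(bg_env[variables], classes=best.classes,
                                             n_hinge_knots=cfg.n_hinge_knots)
        pdm = expander.transform(pres_env.loc[train, variables])
        m = fit_maxent(pdm, bdm, background_weights=bg_weights, beta=best.beta,
                       expander=expander)
        s_test = logistic_suitability(m, pres_env.loc[~train, variables])
        s_bg = logistic_suitability(m, bg_env[variables])
        fold_aucs.append(roc_auc(s_test, s_bg))
        heldout_scores[~train] = logistic_suitability(best.model,
                                                      pres_env.loc[~train, variables])
    train_scores = logistic_suitability(best.model, pres_env[variables])
    thr = omission_thresholds(train_scores, rates=(0.0, 0.10))
    sens = {r: omission_sensitivity(heldout_scores, t) for r, t in thr.items()}
    omis = {r: 1.0 - s for r, s in sens.items()}
    proc = partial_roc_ratio(pred_raster, train_scores,
                             E=cfg.pauc_expected_omission, reps=cfg.pauc_reps,
                             boot_prop=cfg.pauc_boot_prop,
                             seed=stage_seed(cfg.seed, f"pauc:{role}"))
    return EvalResult(
        auc_cv_mean=float(np.mean(fold_aucs)), auc_cv_sd=float(np.std(fold_aucs, ddof=1)),
        fold_aucs=[float(a) for a in fold_aucs],
        pauc_ratio_mean=proc.ratio_mean, pauc_ratio_sd=proc.ratio_sd, pauc_p=proc.p_value,
        thresholds=thr, test_sensitivity=sens, test_omission=omis, folds=folds, seed=seed,
    )


def run_pipeline(config: PipelineConfig,
                 study: SyntheticStudy | None = None) -> AnalysisReport:
    """Run the full analysis; returns the report (artifacts via write_report).

    ``study`` may inject a pre-generated synthetic study; by default one
    is generated from ``config.study`` with a seed derived from the
    pipeline seed.
    """
    provenance: list = []
    current = "generate_study"
    try:
        if study is None:
            overrides = dict(config.study)
            overrides.setdefault("seed", stage_seed(config.seed, "study"))
            study = generate_invasion_study(VirtualSpeciesConfig(**overrides))
        provenance.append({"stage": current, "delta": study.delta,
                           "n_presences": study.config.n_presences,
                           "landscape": [study.config.n_rows, study.config.n_cols]})

        current = "prepare_occurrences"
        nat_occ, nat_env, nat_bg, nat_bg_env, nat_w = _prep_range(
            study.native.occurrences, study.native, config, "native")
        inv_occ, inv_env, inv_bg, inv_bg_env, inv_w = _prep_range(
            study.invaded.occurrences, study.invaded, config, "invaded")
        provenance.append({"stage": current,
                           "native_log": nat_occ.log, "invaded_log": inv_occ.log})

        current = "screen_variables"
        pooled_bg = pd.concat([nat_bg_env, inv_bg_env], ignore_index=True)
        corr = correlation_matrix(pooled_bg)
        variables = prune_collinear(corr, keep_priority=config.variable_priority,
                                    threshold=config.corr_threshold)
        provenance.append({"stage": current, "retained_variables": variables})

        current = "fit_models"
        # regional: invaded-range only; global: native + invaded, pooled background
        glob_pres = pd.concat([nat_env, inv_env], ignore_index=True)
        glob_bg = pooled_bg
        glob_w = None
        if nat_w is not None and inv_w is not None:
            glob_w = np.concatenate([nat_w, inv_w])
        roles = {
            "regional": (inv_env, inv_bg_env, inv_w),
            "global": (glob_pres, glob_bg, glob_w),
        }
        ranked = {role: _fit_role(role, pe, be, w, variables, config)
                  for role, (pe, be, w) in roles.items()}
        best = {role: r[0] for role, r in ranked.items()}
        provenance.append({"stage": current, "candidates": {
            role: [{"name": c.name, "aicc": None if not np.isfinite(c.aicc) else float(c.aicc),
                    "k": c.k, "rank": c.rank, "excluded": c.excluded} for c in r]
            for role, r in ranked.items()}})

        current = "evaluate"
        pred = {role: predict_raster(best[role].model, study.invaded.stack)
                for role in roles}
        performance, contributions = {}, {}
        for role, (pe, be, w) in roles.items():
            ev = _evaluate_role(role, best[role], pe, be, w, variables,
                                pred[role], config)
            performance[role] = {
                "model": best[role].name, "beta": best[role].beta,
                "classes": list(best[role].classes),
                "aicc": float(best[role].aicc), "k": best[role].k,
                **ev.to_dict(),
            }
            vi = variable_importance(best[role].model, pe[variables], be[variables],
                                     seed=stage_seed(config.seed, f"importance:{role}"))
            contributions[role] = {v: float(c) for v, c
                                   in vi["percent_contribution"].items()}
        provenance.append({"stage": current})

        current = "niche_overlap"
        all_names = study.native.stack.names
        nat_env_all = nat_env[all_names] if set(all_names) <= set(nat_env) else nat_env
        overlaps = []
        res = compare_niches(
            nat_env_all, inv_env[nat_env_all.columns],
            nat_bg_env[nat_env_all.columns], inv_bg_env[nat_env_all.columns],
            reps=config.overlap_reps, seed=stage_seed(config.seed, "overlap"),
            R=config.overlap_grid_R, label="native_vs_invasive",
        )
        overlaps.append(res.to_dict())
        provenance.append({"stage": current, "contrasts": [r["label"] for r in overlaps]})

        current = "invasion_stages"
        p_reg = logistic_suitability(best["regional"].model, inv_env[variables])
        p_glob = logistic_suitability(best["global"].model, inv_env[variables])
        point_stages = classify_stage(p_reg, p_glob, tau=config.stage_tau)
        stage_map = classify_stage_raster(pred["regional"], pred["global"],
                                          tau=config.stage_tau)
        stage_summary = {
            "tau": config.stage_tau,
            "point_counts": {s: int(np.sum(point_stages == s))
                             for s in ("stabilizing", "colonization", "adaptation", "sink")},
            "cell_counts": stage_map.counts,
            "legend": stage_map.legend,
        }
        provenance.append({"stage": current})
    except Exception as exc:       # noqa: BLE001 — re-raise with stage context
        raise PipelineError(current, provenance, exc) from exc

    return AnalysisReport(
        config=config.to_dict(), config_hash=config.hash(), version=__version__,
        provenance=_roundtrip(provenance), performance=_roundtrip(performance),
        contributions=_roundtrip(contributions), overlaps=_roundtrip(overlaps),
        stage_summary=_roundtrip(stage_summary),
    )


def write_report(report: AnalysisReport, out_dir) -> list[str]:
    """Write the JSON report and a human-readable summary; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    json_path = os.path.join(out_dir, "report.json")
    with open(json_path, "w") as fh:
        fh.write(report.canonical_json())

    lines = [
        f"nicheshift {report.version}  (config hash {report.config_hash})",
        "",
        "Model performance",
        "-----------------",
    ]
    for role, perf in report.performance.items():
        lines += [
            f"{role}: {perf['model']} (features {'+'.join(perf['classes'])}, "
            f"beta={perf['beta']:g}, AICc={perf['aicc']:.2f}, k={perf['k']})",
            f"  AUC_cv = {perf['auc_cv_mean']:.3f} +/- {perf['auc_cv_sd']:.3f}"
            f"   pAUC ratio = {perf['pauc_ratio_mean']:.3f} +/- {perf['pauc_ratio_sd']:.3f}"
            f" (p={perf['pauc_p']:.3f})",
            f"  test sensitivity @0%/10% OR = "
            f"{perf['test_sensitivity']['0.0']:.3f} / {perf['test_sensitivity']['0.1']:.3f}",
        ]
    lines += ["", "Variable contributions (%)", "--------------------------"]
    for role, contrib in report.contributions.items():
        top = sorted(contrib.items(), key=lambda kv: -kv[1])
        lines.append(f"{role}: " + ", ".join(f"{v}={c:.1f}" for v, c in top))
    lines += ["", "Niche overlap", "-------------"]
    for ov in report.overlaps:
        lines += [
            f"{ov['label']}: Schoener's D = {ov['schoeners_d']:.3f} "
            f"(equivalency p = {ov['p_equivalency']:.3f}, similarity p = {ov['p_similarity']:.3f},"
            f" {ov['n_randomizations']} randomizations)",
            f"  expansion = {ov['expansion']:.3f}, stability = {ov['stability']:.3f},"
            f" unfilling = {ov['unfilling']:.3f},"
            f" centroid shift = ({ov['centroid_shift'][0]:.2f}, {ov['centroid_shift'][1]:.2f}) PC units",
        ]
    lines += ["", "Invasion stages", "---------------",
              f"tau = {report.stage_summary['tau']:g}",
              "points: " + ", ".join(f"{k}={v}" for k, v in
                                     report.stage_summary["point_counts"].items()),
              "cells:  " + ", ".join(f"{k}={v}" for k, v in
                                     report.stage_summary["cell_counts"].items())]
    txt_path = os.path.join(out_dir, "summary.txt")
    with open(txt_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return [json_path, txt_path]
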