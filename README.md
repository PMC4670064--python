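# nicheshift

Invasion-niche analysis for presence-background data: maximum-entropy
species distribution modelling with model selection and partial-ROC
evaluation, PCA-env quantification of realized climatic niche shifts
(Schoener's *D* with randomization tests), and regional-vs-global
invasion-stage classification. The package targets invasion ecologists
who need to ask, from occurrence compilations and gridded climate: *where
could an invader establish, has its realized climatic niche shifted
between native and invaded ranges, and which populations are stabilizing,
colonizing, adapting, or sinks?*

Every method is exercised end-to-end on a built-in **virtual-species
generator** — paired synthetic landscapes with monthly climate, a known
suitability function, a controllable niche shift and biased sampling — so
each estimator can be validated against ground truth.

## Methods at a glance

**Maximum-entropy SDM.** Relative suitability is a Gibbs distribution over
background cells, `q(x) = w(x) exp(λ·f(x)) / Z_w`, fitted by maximizing
the L1-penalized presence log-likelihood

```
(1/m) Σ_presences λ·f(x)  −  log Z_w  −  β Σ_j s_j |λ_j|
```

with linear/quadratic/product/hinge features `f`, per-feature penalty
scales `s_j`, and regularization multiplier β. Candidate feature/β
settings are ranked by AICc; models with implausible (multimodal)
response curves are screened out. Outputs include the logistic
suitability `e^H q̃ / (1 + e^H q̃)`, permutation-based variable
contributions, k-fold cross-validated AUC, the partial-ROC ratio, and
omission-rate thresholds.

**PCA-env niche overlap.** The two ranges' climates are projected onto
the first two principal components of their pooled backgrounds; on a
shared grid the kernel-smoothed occurrence density is corrected by the
background density, giving occupancy surfaces `o`. Overlap is Schoener's
`D = 1 − ½ Σ |o₁ − o₂|`, tested by niche equivalency and similarity
randomizations, with expansion / stability / unfilling indices and the
niche-centroid shift.

**Invasion stages.** Each occurrence (or map cell) is placed in a
quadrant of the (regional model, global model) probability plane:
stabilizing, colonization, adaptation, or sink.

## Worked example

```python
from nicheshift import PipelineConfig, run_pipeline, write_report

cfg = PipelineConfig(seed=1)          # default 200x200 virtual-species study
report = run_pipeline(cfg)
write_report(report, "out")
```

The `out/summary.txt` for this config reads (abridged):

```
Model performance
-----------------
regional: LQH_b1.5 (features linear+quadratic+hinge, beta=1.5, AICc=3804.17, k=13)
  AUC_cv = 0.669 +/- 0.055   pAUC ratio = 1.274 +/- 0.065 (p=0.000)
  test sensitivity @0%/10% OR = 1.000 / 0.900

Niche overlap
-------------
native_vs_invasive: Schoener's D = 0.812 (equivalency p = 1.000, ...)
  expansion = 0.006, stability = 0.994, unfilling = 0.009, ...
```

Reading this: the hinge-feature candidate at β = 1.5 won the AICc
ranking with 13 active coefficients; cross-validated AUC of 0.67 and a
partial-ROC ratio of 1.27 (> 1, p ≈ 0) say the model discriminates
presence sites from background much better than chance; 90% of held-out
presences score above the 10%-training-omission threshold. The default
study simulates *no* niche shift, and the analysis agrees: overlap
between the two ranges' occupancy surfaces is high (D = 0.81), the
equivalency test finds no evidence of lower-than-chance overlap
(p = 1.0), and almost all invaded-range occupancy lies inside the native
niche (stability 0.99).

The same pipeline is scriptable from the shell
(`nicheshift run-all --config study.yaml`), and each step is exposed as
its own subcommand: `simulate`, `derive-climate`, `prep-occurrences`,
`fit-sdm`, `evaluate`, `niche-overlap`, `stages`.

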