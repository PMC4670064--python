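# Methods

## Scope and data model

The package analyses presence-background occurrence data against gridded
climate. Rasters are square-celled grids with an upper-left-origin
geotransform and a boolean nodata mask, exchanged on disk as ESRI ASCII
grids (one file per variable on a shared frame). Geographic coordinates
(`crs_tag = "WGS84"`) are projected to the World Cylindrical Equal Area
plane (authalic radius, standard parallel 0) before any distance, kernel
or density computation; synthetic landscapes are already planar with
coordinates in kilometres.

## Climate predictors

Twenty predictors are derived from monthly tmin/tmax/tmean (°C) and
precipitation (mm): the 19 standard bioclim summaries plus annual
degree-days above a 10 °C base. Conventions fixed here:

* quarters are 3 consecutive calendar months with wrap-around; extreme
  quarters (wettest/driest/warmest/coldest) break ties at the earliest
  window;
* bio3 = (bio2/bio7) × 100; bio4 = population SD of monthly means × 100;
  bio15 = SD of monthly precipitation / (1 + bio12/12) × 100;
* degree-days use calendar month lengths in a 365-day year:
  Σ_m days_m · max(0, tmean_m − 10). No leap years, no sub-monthly
  interpolation — at monthly input resolution a finer convention would be
  false precision.

Collinearity screening removes one of each pair with Pearson |r| ≥ 0.80
(strict: 0.79 keeps both), walking a user-supplied keep-priority order
greedily, so among a correlated set the highest-priority variable
survives. The screen is idempotent. Extraction at points is nearest-cell
(no interpolation), matching the positional precision of typical
occurrence records at ~1-km grids.

## Occurrence preparation

Records carry a provenance log; every filtering step appends one entry
whose input/retained/removed counts reconcile exactly. Steps: CSV
validation (malformed rows rejected by line number), grid deduplication
(at most one record per cell, first by input order), spatial thinning
(greedy maximal-retention: repeatedly drop the record with most
neighbours inside the minimum distance, seeded tie-breaks), a Gaussian
kernel-density **bias surface** of sampling effort (rescaled to max 1,
floored at 1e-6), and background sampling from the accessible-area mask —
without replacement, uniformly or weighted by the bias surface.

Defaults that the underlying field literature leaves open: the thinning
distance (10 km for geographic data, 1 km on synthetic landscapes at
0.4 km cells) and the bias-surface bandwidth (2× the thinning distance).
Both are config parameters. The bias surface can enter the model as
weighted background *selection* (default), as fitting *weights*, or not
at all.

## Maximum-entropy model

Predictors are min-max scaled to [0,1] on the background. Feature classes:
linear (x), quadratic (x²), product (x_i x_j), and hinge at
evenly spaced knots k — forward max(0,(x−k)/(1−k)) and reverse
max(0,(k−x)/k), 50 knots per variable by default (10 in the pipeline
default config, which keeps candidate grids fast without changing the
model family).

The fit minimizes `log Z_w − mean_presence(λ·f) + β Σ s_j |λ_j|` where
`Z_w = Σ_background w e^{λ·f}`. Penalty scales follow the reference
MaxEnt convention: a per-class base value interpolated in the presence
count m (linear 1.0→0.05, quadratic 1.3→0.05, product 2.6→0.05 over
m = 0…100; hinge 0.5), multiplied by the feature's background SD / √m.
The optimizer is monotone FISTA: proximal soft-threshold steps with
backtracking line search, Nesterov momentum, and fallback to a plain
proximal step whenever the accelerated candidate would increase the
objective — so the objective trace is non-increasing by construction.
Convergence is an absolute objective change below 1e-7 (max 5,000
iterations; exceeding them raises with the trace attached). At β = 0 with
linear features the optimum moment-matches: E_q[f] equals the presence
mean of f (verified to 1e-6 in tests, and against a brute-force grid
search of the penalized likelihood).

Outputs: raw probabilities q (sum to 1 over the training background),
logistic suitability `e^H q̃/(1 + e^H q̃)` with H the entropy of the
*unweighted* raw distribution — this choice makes a null (all-zero) model
score exactly 0.5 everywhere and corresponds to the standard prevalence-
0.5 convention. Raster projection clamps predictors to training bounds by
default and propagates nodata.

Variable contributions use permutation importance — the drop in training
gain when one variable's values are permuted across presence + background
rows (3 permutations, seeded), clipped at zero and normalized to 100%.
The reference implementation's per-update gain attribution is
optimizer-specific and is deliberately not reproduced. Jackknife
(only-variable / without-variable refits) is available on request.

Model selection: candidates over feature-class sets and β (default grid:
LQH β1.5, LQP β2.5, LQPH β2.5; β commonly swept 1–3) are ranked by
AICc = 2k − 2lnL + 2k(k+1)/(n−k−1), with lnL the presence log-likelihood
of the raw distribution renormalized over the full landscape and k the
nonzero-coefficient count. Candidates with k ≥ n−1 or response curves
showing more than `max_interior_modes` (default 3) interior local maxima
are excluded.

## Evaluation

k-fold cross-validation (default 10) refits per fold and scores held-out
presences against the background (rank-based AUC, ties half). Because the
"negatives" are background, AUC is an index of discrimination from
availability, not absence. The partial-ROC ratio bootstraps test points
(50% with replacement, 1,000 reps by default; both follow the cited
method's common usage and are configurable), computes the partial AUC of
the sensitivity-vs-predicted-area curve over the region with sensitivity
≥ 1−E, and divides by the random expectation (the diagonal over the same
region); a perfect model at E = 0 gives exactly 2. Omission thresholds
are quantiles of training presence scores (0% = minimum); both test
sensitivity and test omission are reported explicitly, since the two are
easily conflated in summary tables.

## PCA-env niche comparison

The niche space is the first two axes of a correlation-matrix PCA
(variables standardized — they mix °C, mm and degree-days) fitted on the
pooled backgrounds of the two ranges being contrasted. Occurrence and
background densities are estimated on a shared R×R grid (default 100)
spanning the pooled point cloud plus a 5% margin, by cell-count
histograms smoothed with a Gaussian kernel (bandwidth per axis from the
bivariate normal reference rule on the pooled background, so both
densities share one smoothing). Occupancy is z_occ/z_env on available
cells, normalized to sum 1.

**Availability floor.** Cells whose background density falls below 5% of
its maximum are treated as unavailable. The floor is not cosmetic:
parameter-recovery simulations show that a near-zero floor lets the
occurrence/background ratio explode in barely-sampled corners of the
environment space, inflating centroid-shift estimates by ~15%; at the 5%
floor a true 2-SD shift is recovered within a few percent and overlap
statistics are essentially unchanged.

Schoener's D = 1 − ½ Σ|o₁ − o₂|. The equivalency test pools and
reassigns occurrences (original group sizes) and recomputes D; the
similarity test translates one range's occurrence cloud to a random
background point within its own background (wrapped into the background
box). Both lower- and upper-tail p-values are reported,
p = (count + 1)/(reps + 1), with 100 randomizations by default. The
randomization count follows the common reporting convention; which of
the two tests a given study means by "randomization test" is often
ambiguous, so both are always computed.

Niche dynamics follow the analogue-climate convention: expansion (invasive
occupancy where native occupancy is ~0), stability (1 − expansion) and
unfilling (native occupancy where invasive is ~0) are computed on cells
available in both backgrounds, each surface renormalized there;
"unoccupied" means at or below the 5% quantile of that surface's positive
values — a simplification of the intersection convention in the cited
framework. The centroid shift is the difference of occupancy-weighted
mean PC positions.

## Invasion stages

With τ (default 0.5, the conventional illustrative threshold; "high"
means ≥ τ): both models ≥ τ → stabilizing; regional < τ ≤ global →
colonization; global < τ ≤ regional → adaptation; both < τ → sink. The
four categories partition [0,1]² exactly. The pipeline pairs the
invaded-range-only model (regional) with the native+invaded model
(global).

## Virtual-species generator

Landscapes are band-limited sums of 8 seeded random plane waves
(dominant wavelength = smoothness × extent, default 0.25), chosen over
FFT Gaussian random fields for dependency-light, platform-stable
reproducibility. Monthly temperature follows an annual cosine cycle
(July peak) around a smooth mean field, with a positive diurnal-range
field guaranteeing tmin ≤ tmean ≤ tmax; precipitation is a positive
log-smooth field with its own seasonal cycle and a random peak month.

The true niche is logistic-quadratic,
s = 1/(1+exp(−[a − Σ_v ((x_v−μ_v)/σ_v)²])), with breadth σ_v = 0.75
background SD and intercept a = 4 — a unimodal niche occupying a
realistic minority of each landscape. The niche shift δ separates the two
optima by δ pooled-background SD units along the first principal axis of
the pooled standardized background, so the truth is expressed in the same
space the overlap analysis estimates in. Presence sampling draws cells
with probability ∝ suitability × sampling bias (default: an east-west
exponential effort gradient, mimicking uneven survey effort), with
replacement and within-cell jitter.

Default study scale: 200×200 cells at 0.4 km, 5 predictor variables, 250
presences per range — the full pipeline runs in well under a minute on
one CPU. Validation simulations (acceptance tests and script) use
100×100-cell studies with 200 presences and 2,000-point background
samples per range, and 20 seeds per condition; these sizes give stable
means while keeping the whole recovery sweep to a few seconds.

**What the generator does and does not emulate.** It reproduces the
structural features the methods rely on — smooth multi-variable climate
with realistic cross-correlations, a known unimodal niche, availability
differences between ranges, spatial sampling bias, duplicate records
within cells. It does not emulate dispersal limitation, biotic
interactions, temporal spread, observation error in coordinates, or
non-equilibrium occupancy within a range; passing tests therefore
demonstrate estimator correctness and calibration under the stated
generative model, not robustness to every pathology of real compilations.

## Numerical and design notes

* All randomness flows from explicit seeds; the pipeline fans one seed
  into per-stage seeds via CRC32 of `"<seed>:<stage>"`, so stages can be
  rerun independently and the report hash is reproducible.
* Ties in quarter selection, deduplication and AICc ranking resolve to
  the earliest/first/lowest deterministic option.
* Zero-variance columns are dropped (features, PCA) or flagged
  (correlation) with warnings rather than erroring, since constant layers
  are common on masked rasters.
* Degenerate inputs raise with specific messages: empty accessible area,
  all points off-grid, all-zero suitability, all candidates excluded,
  non-convergence (with the objective trace attached).

## Known limitations

* The fitting objective matches the reference MaxEnt formulation, but
  equivalence with the Java implementation is claimed only for behaviours
  covered by the oracle tests (penalized-likelihood optimum, moment
  matching, logistic transform identities), not byte-level output.
* Threshold and categorical feature classes are not implemented.
* The equal-area transform assumes the authalic sphere; for sub-km
  precision at high latitudes an ellipsoidal projection would be needed.
* Only two PCA axes are supported in the overlap analysis by design;
  niche differences orthogonal to PC1/PC2 are invisible to it.
* ESRI ASCII is the only raster format; binary GeoTIFF I/O is out of
  scope.
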