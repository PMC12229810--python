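# Methods

`rangestack` implements a two-tier (stacked-generalization) species
distribution modelling workflow for presence-background data, with
optional integration of an expert range map, and validates it end to end
on a simulated species whose range is truncated by a dispersal barrier.
This note documents the models, the main parameters and their defaults,
the numerical conventions, and what the simulation does and does not
emulate.

## The modelling problem

Opportunistic occurrence records describe where a species has been seen;
they carry fine-grained information about species-environment
associations but none about range limits imposed by dispersal barriers.
Expert range maps encode those limits coarsely, at the cost of
commission error (mapped area the species does not occupy) and omission
error (occupied fringe left unmapped).  A model trained only on
occurrences and environment will predict any environmentally suitable
habitat as occupied — including habitat the species cannot reach.  The
workflow here combines both data types: four base SDMs are fitted to
presences and background points, and a logistic meta-learner combines
their predictions, optionally together with each location's distance to
the expert range polygon, into a final suitability surface.

## Data preparation

- **Cleaning/thinning.**  Records without environmental coverage are
  dropped; records are thinned to at most one per `thin_resolution` cell
  (default 0.05°, the working resolution of typical marine predictor
  stacks).  Thinning keeps the first record per cell in input order, so
  it is deterministic and idempotent without a seed.
- **Calibration area.**  All grid cells whose centre lies within
  `buffer_km` (default 1000 km, great-circle on an R = 6371 km sphere)
  of any presence.  Models are fitted and mapped only inside it.
- **Background.**  `n_background` (default 10,000) points drawn
  uniformly over calibration cells (cells with replacement, uniform
  jitter within the cell).  One background sample is shared by all four
  algorithms; background rows carry weight 1 in every likelihood
  (standard presence-background practice).  Background points may fall
  in presence cells.
- **Collinearity screen.**  Pairwise Pearson correlations are computed
  over calibration cells; while any pair exceeds `corr_threshold`
  (default 0.7), the non-protected predictor with the highest mean
  absolute correlation is dropped.  The `keep_list` is the reproducible
  stand-in for choosing among correlated predictors by ecological
  knowledge; two protected but mutually collinear predictors are an
  error rather than a silent override.

## Base learners

All four consume one shared training table (predictor columns, 0/1
label, 1..10 fold assignment), so downstream per-fold comparisons are
paired.

- **GLM.**  Binomial-logit regression on linear + quadratic terms;
  backward elimination from the full second-order polynomial, accepting
  the single removal that most lowers AIC until none does.  Perfect
  separation falls back to a lightly ridge-penalized fit with a warning.
- **GAM.**  Additive binomial model with one B-spline smooth of basis
  dimension 3 per predictor (quadratic splines, 3 basis functions — the
  small-basis analogue of `mgcv`'s `k = 3`).  The penalty weight is
  selected by GCV over the grid {0, 1, 10, 100}; fold refits reuse the
  full-data choice.  Spline bases are undefined beyond the training
  range, so prediction clips new values to it (constant extrapolation).
  Constant predictor columns carry no information and are excluded from
  the smoother; their contribution is identically zero.
- **MaxEnt.**  Implemented as L1-penalized binomial regression on a
  feature expansion of the standardized predictors — linear (L),
  quadratic (Q), hinge (H; 10 interior quantile knots per predictor,
  both orientations), product (P) — which is the standard
  presence-background reformulation of maximum-entropy density
  estimation.  The per-feature penalty is
  `rm x c_class x n_rows / sqrt(n_presences)` with class weights
  c = {L: 0.05, Q: 0.05, H: 0.5, P: 0.1}, echoing conventional MaxEnt
  regularization defaults: hinge features are penalized an order of
  magnitude harder than linear ones, and penalties weaken as presences
  accumulate.  Standardizing each predictor *before* building features
  makes predictions invariant to affine rescaling of the inputs.
  Output is the complementary log-log transform of the exponential
  model, normalized over the training background (cloglog output),
  clipped to [0, 1].
- **Random forest.**  Ensemble of classification trees in which every
  tree is trained on a bootstrap of the presences plus an equal-size
  random subsample of the background (down-sampling; asserted per
  tree), neutralizing the ~1:30 class imbalance.  Suitability is the
  mean leaf presence fraction across trees.  Key parameters: number of
  trees (default 500), predictors per split (default floor(sqrt p)),
  minimum terminal node size (default 10).  Response-curve smoothness
  is governed by the terminal node size: small leaves give locally
  noisy partial-dependence profiles, so response-shape analyses use
  larger nodes (100 at n ~ 3000).

**Tuning.**  MaxEnt candidates span feature classes {L, LQ, H, LQH,
LQHP} x regularization multipliers {0.5, 1, 2, 3, 4}; RF candidates
span trees {500, 1000} x m_try {2, floor(sqrt p), p-1} x node size
{1, 5, 10}.  Each candidate's 10% omission rate (OR10: threshold at the
10th percentile of training-presence predictions, omission measured on
validation presences) and AUC are averaged over the shared 10 folds.
Selection keeps the best decile by OR10 (ties with the cutoff included,
so an all-tied field passes through) and returns the max-validation-AUC
member.  The default pipeline configuration fits fixed mid-grid
hyperparameters (MaxEnt LQH, rm = 1; RF 500 trees, sqrt-p m_try, node
size 10) and grid tuning is opt-in (`--tune`), which keeps the
repeated-simulation experiment affordable.

## Expert-range integration

The expert polygon becomes a continuous per-cell predictor: 0 for cell
centres inside or on the polygon, otherwise the great-circle distance
(km, R = 6371) to the nearest point of the polygon boundary, densified
to steps of at most 0.05° so the nearest-vertex approximation is
accurate to well under a cell width.  Kilometres are the declared unit;
the meta-learner's distance coefficient is per-km.  Multipolygon
distance is to the nearest part.

## Stacking

The meta-learner is a maximum-likelihood logistic regression of the
label on the four base-model predictions (untransformed), plus the
distance predictor in the expert-informed variant.  The default
meta-training table is **out-of-fold**: each row's base predictions come
from models refitted without that row's fold (10 refits per algorithm),
which keeps the meta-learner from rewarding base-model overfitting;
in-sample stacking is available for comparison and the mode is recorded
on the fit.  Wald p-values are reported per coefficient.

Base predictions from flexible learners are often strongly
inter-correlated (GLM and GAM fit nearly the same surface); when the ML
fit fails to converge or runs away along a near-null direction, the fit
falls back to IRLS with a small ridge (lambda = 1e-4), which pins
unidentified directions (their standard errors become huge, so they are
correctly reported as non-significant) while leaving well-identified
coefficients and their p-values essentially unchanged.  The design
condition number is computed on every fit and near-collinearity is
warned about.

## Evaluation

- **Continuous Boyce index** (headline metric for presence-background
  models): 101 moving windows of width one tenth of the pooled
  suitability range; per window the presence/background frequency ratio
  F; runs of consecutive equal F values are collapsed to their first
  window (the standard continuous-Boyce convention); the index is the
  Spearman correlation of F against the window midpoint.  An exactly
  flat F profile is a random prediction and scores 0; constant
  suitability is undefined and raises.
- **AUC**: rank-based (Mann-Whitney), ties counted one half.
- **TSS**: max over candidate thresholds (midpoints of sorted unique
  values, plus one below the minimum) of sensitivity + specificity - 1.
- **Cross-validation**: presences and background each split into 10
  random folds (not spatially blocked — an explicit non-goal); all six
  models (4 base + 2 ensembles) are refitted per fold with their chosen
  hyperparameters and scored on the held-out fold; per-fold Boyce uses
  the held-out background rows as the expectation sample.  Within each
  fold's training set the ensembles are stacked out-of-fold by reusing
  the remaining folds' structure.
- **Model comparison**: exact two-sided Wilcoxon signed-rank test on
  the 10 paired per-fold differences (zeros dropped, average ranks for
  ties; exact null by dynamic programming for n <= 25, tie-corrected
  normal beyond).
- **Binarization**: suitable iff suitability >= the 10% omission
  threshold, defined as the ceil(0.1 n)-th smallest training-presence
  prediction (conventions differ across software; this one guarantees
  at least 90% of training presences are retained).
- **Range summaries**: spherical cell areas
  R² Δλ (sin φ_top − sin φ_bottom); southernmost suitable cell-centre
  latitude; % of suitable area whose cell centre is covered by the
  expert polygon.

## The virtual species

The simulator is the test bed for the whole workflow: every quantity
has a known truth.

- **Environment**: four layers on a 120x120-cell, 0.1° grid (a 12°x12°
  coastal domain), each a planar gradient (direction rotating with layer
  index) plus spatially autocorrelated noise made by Gaussian-smoothing
  white noise (sigma = 5 cells, weight 0.5), standardized to mean 0,
  sd 1.  A Gaussian-smoothed field is a cheap, exactly reproducible
  stand-in for a Gaussian random field with comparable autocorrelation
  range.
- **Truth**: suitability = logistic(b0 + Σ beta_j x_j + Σ gamma_j x_j²)
  with b0 = 0.5, beta = (1.2, 0.3, 0.4, 0), gamma = (-1, -0.2, 0,
  -0.3): the dominant (longitudinal) layer forms a high-suitability band
  that crosses the barrier latitude, while the latitudinal layer gets
  only a weak coefficient so the environment alone does not reveal the
  barrier.  Occupancy is Bernoulli(suitability) north of the barrier
  (24° N, one third up the domain — a latitude line mirroring an
  estuarine freshwater-plume barrier) and identically 0 south of it.
  Generation asserts that suitable-but-unoccupied habitat exists south
  of the barrier; without it the headline experiment would be vacuous.
- **Sampling**: 300 presences drawn without replacement from occupied
  cells with weight suitability^1 x a fixed west-coast effort kernel
  (exp(-2 (lon - west)/span)), jittered within the cell — emulating the
  suitability- and accessibility-biased character of opportunistic
  records.
- **Expert polygon**: the union of occupied cells, opened
  morphologically at 10 km (omission error: scattered marginal
  occurrences fall outside the mapped range, as they do for real expert
  maps — with these defaults roughly 4-5% of presences are outside,
  the same order as published expert-map omission rates) and then
  buffered outward by 50 km (commission error).  The omission step is
  not cosmetic: with every presence inside the polygon, distance > 0
  would perfectly predict absence, the meta-learner's distance
  coefficient would diverge, and its significance would be
  unestimable.  Buffers are applied in degrees of latitude-equivalent
  arc, adequate at these scales.

**What the simulation does not emulate**: real coastline geometry and
land masking, ocean-current dispersal, temporal dynamics, observation
error in coordinates, spatially varying detection, and the specific
covariance structure of real marine predictor stacks.  Passing tests
therefore show that the machinery behaves as designed under a faithful
abstraction of the barrier problem — not that any particular real
species is modelled well.

## Problem sizes and numerical choices

The repeated-simulation experiment uses the full default configuration
(120x120 grid, 300 presences, 10,000 background points, 500-tree
forests) across ten worlds.  The cross-validation demonstrations and
the determinism checks use a half-size domain (60x60, 100 presences,
1,000 background, 200 trees), which preserves the barrier geometry at a
fraction of the cost.  Tolerances: metric implementations match
brute-force oracles to 1e-9; MaxEnt affine invariance holds to 1e-6
(solver tolerance 1e-10); map/table prediction consistency to 1e-9.
All randomness flows from explicit integer seeds; a rerun with the same
configuration reproduces every table byte for byte.

## Known limitations

- The distance predictor enters the meta-learner linearly on the logit
  scale; a threshold or saturating response would need a different
  basis.
- Wald p-values from the ridge fallback are approximate near complete
  separation (they are conservative for the affected directions).
- The omission threshold and Boyce windows are conventions; both are
  parameterized and logged, but other software may differ in detail.
- Expert-map quality is assumed reasonable: a polygon that misses the
  true range wholesale would make the distance predictor misleading, a
  caveat inherent to the data-integration idea itself.
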