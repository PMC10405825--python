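# Methods

`enmpipe` implements a complete species-distribution-modelling and
conservation-planning chain for a single species on a geographic lat/lon
raster lattice: collinearity screening of candidate predictors, a
regularized maximum-entropy (MaxEnt-type) niche model tuned by AICc over a
feature-class x regularization grid, suitability classification and
range-change analysis across climate scenarios, niche overlap and breadth
metrics, and Marxan-style minimum-set reserve selection. A synthetic-data
module generates study systems with known ground truth so that every stage
can be validated against an oracle.

## The maximum-entropy model

Let `f(x)` be a vector of features derived from the environmental values of
a cell and `Λ = (λ_j)` coefficients. The model is the Gibbs distribution
over the background cells

    raw(x) = exp(λ · f(x)) / Z_λ ,   Z_λ = Σ_background exp(λ · f(x)),

fitted by maximizing the L1-penalized log-likelihood of the presence sample

    (1/m) Σ_presences λ·f(x_i)  −  ln Z_λ  −  Σ_j β_j |λ_j| .

Per-feature penalties follow the standard MaxEnt convention
`β_j = RM · β_class(m) · sd_j(presences)/√m`, where `β_class(m)` linearly
interpolates the published default anchors per feature class
(linear/quadratic/product: 1.0 at m=10, 0.2 at m=30, 0.05 at m=100; hinge:
0.5; threshold: 2.0 at m=0 to 1.0 at m=100) and `RM` is the user-facing
regularization multiplier. The presence standard deviation is floored at
1e−4 so every feature carries a positive penalty.

Features span the five classic classes over min–max-scaled variables:
linear, quadratic, pairwise products, forward/reverse hinges and step
thresholds, with hinge/threshold knots at evenly spaced background
quantiles (30 by default; 10 in the tuning grid and tests to keep the
candidate count proportionate to the test-scale background). At projection
time variables are clamped to the training range.

### Optimizer

Cyclic coordinate descent. For coordinate `j`, a Newton step on the smooth
part is soft-thresholded at `β_j/h_j` (with `h_j` the current background
variance of the feature), clipped to ±5, and backtracked (halving) until
the exact penalized objective does not decrease — so the objective is
non-decreasing across updates by construction. The background distribution
`w` is maintained incrementally (`w ∝ w·exp(δ f_j)`) and resynchronized
against drift once per sweep via a full log-sum-exp. One coordinate update
counts as one iteration; the default cap is 10 000 iterations and
convergence is declared when the relative objective change over a full
sweep falls below 1e−5. On one- and two-feature problems the solution
matches a dense grid search of the same objective to 1e−3 (tested).

### Output scales

`raw` sums to 1 over the estimation background (presence cells are added
to the background, the standard convention). The logistic output is
`e^H·raw/(1 + e^H·raw)` with `H` the entropy of the fitted background
distribution — the familiar suitability in [0,1] with implied prevalence
0.5. Cloglog output is not implemented.

## Model tuning

Candidates cross the six feature-class combinations {L, LQ, H, LQH, LQHP,
LQHPT} with multipliers 0.5–4.0 in steps of 0.5 (48 models). Each
candidate is evaluated by

* bootstrap-replicated AUC: each of 10 replicates resamples occurrence
  cells with replacement, splits the distinct resampled cells 75/25 into
  train/test, fits on train and scores both partitions against a fixed
  background (the AUC is the Mann–Whitney rank form with ties counted ½);
* AICc of a fit to all occurrences, with the raw density renormalized over
  the full prediction domain, `k` = number of nonzero coefficients, and
  `AICc = 2k − 2lnL + 2k(k+1)/(n−k−1)` (undefined, reported NaN, when
  `k ≥ n−1`).

The selected model minimizes ΔAICc; ties break by larger
`auc_train − auc_diff_avg`, then fewer feature classes, then smaller RM.

Variable importance is reported three ways: percent contribution (each
accepted coordinate-descent update's objective gain credited to the
feature's parent variable(s), products split evenly), permutation
importance (training-AUC drop after permuting one variable jointly across
presence+background rows, floored at 0 and normalized to 100%), and the
leave-one-variable-out / only-one-variable jackknife of training gain
(`gain = (1/m)Σλ·f − lnZ + ln N`, i.e. improvement over the uniform
model). With L1 regularization, near-duplicate variables are not treated
symmetrically by the fit itself (the penalty parks shared signal on one
member), so the permutation-importance symmetry property holds for equal
coefficients, not for every equivalent optimum.

## Habitat dynamics

Logistic suitability is cut at 0.374 / 0.57 / 0.7 into unsuitable, low,
moderate and high classes (half-open intervals, suitable means
`p ≥ 0.374`); the suitable/unsuitable cut is configurable. Areas weight
each cell by its spherical quadrangle area
`R²·Δλ·(sin φ_top − sin φ_bot)`, `R = 6371.0088 km`, so they vary with
latitude. Between two binarized maps, cell transitions 0→1 / 1→0 / 1→1
give gain / loss / stable areas, and

    percent_gain = 100·gain/current,  percent_loss = 100·loss/current,
    range_change = 100·(gain − loss)/current.

The accounting identities `loss + stable = current` and
`stable + gain = future` hold exactly on unrounded values. Suitable-area
centroids are cell-area-weighted means of suitable-cell centers; the
migration distance between centroids is the WGS84 ellipsoidal geodesic
computed by Vincenty's inverse formula (agreeing with R
`geosphere::distVincentyEllipsoid` to <0.1 m on probe pairs; the
near-antipodal non-convergence region falls back to the spherical great
circle).

## Niche metrics

With `p` a suitability surface normalized to sum 1 over valid cells:
Schoener's overlap `D(p,q) = 1 − ½Σ|p−q|`; Levins breadth
`B1 = ((1/Σp²) − 1)/(n−1)`; Shannon breadth `B2 = (−Σp ln p)/ln n`. The
primary comparison space is geographic. A reduced environment-space mode
projects background cells onto the first two principal axes of their
correlation matrix, bins suitability-weighted cells on a square lattice,
Gaussian-smooths and renormalizes; it is a simplified stand-in for
kernel-based environment-space workflows, not a replica of them, and both
scenarios must be scored with the same axes and lattice to be comparable.

## Reserve selection

Planning units are square blocks of raster cells (25 km nominal edge;
the block size in cells is rounded from the mid-latitude cell width).
Unit cost is its valid-cell land area; the single default feature is the
suitable-habitat area inside the unit. The objective is

    total = Σ_selected cost + BLM·boundary + Σ_k SPF·(shortfall_k/target_k)·G_k

with `target_k` = 30% of the feature total, `boundary` the edge length
between selected and unselected/exterior (exterior edges of selected units
count; the empty selection has boundary 0), and `G_k` the cost of meeting
the target greedily by best amount/cost ratio — a fixed, instance-derived
scale that makes the penalty commensurate with cost, documented here
because Marxan's internal penalty calibration is not public. Optimization
is simulated annealing over single-unit flips (initial temperature =
median |Δ| of random flips, geometric cooling to a 1e−4 floor across the
run), followed by iterative improvement with single flips and pairwise
exchanges — the exchange step is needed because removing an
over-provisioned unit momentarily spikes the shortfall penalty, a barrier
single flips cannot cross. An ensemble of independent runs (100 by
default) yields the best solution and per-unit selection frequencies. On
10-unit instances the ensemble matches exhaustive enumeration in ≥95/100
seeded trials (tested).

## Synthetic study systems

Environmental layers are smooth Gaussian random fields (white noise
convolved with a Gaussian kernel, σ = `smoothness` in cells, z-scored),
whitened exactly and mixed by the Cholesky factor of the target
correlation so the empirical cross-correlation equals the target. The
default stack has 12 layers with an AR(1)-style correlation (ρ = 0.3
between adjacent codes) on a 60×60 lattice of 2.5-arc-minute cells —
test-scale stand-ins for a bioclim+soil+terrain stack. True suitability is
logistic in a linear combination of a subset of layers; presences are
multinomial draws proportional to suitability, placed at cell centers
(with duplicates allowed and a configurable uniform-noise admixture, 10%
by default). "Future" stacks shift named layers additively, optionally
with a north–south gradient that migrates the suitable band poleward;
severity scales the shift across scenarios.

What the generator does *not* emulate: sampling bias, spatially
autocorrelated observation error, categorical predictors, variance changes
under climate scenarios, and real bioclim covariance structure. Passing
tests therefore demonstrate algorithmic correctness and statistical
behavior under controlled conditions, not performance on real occurrence
data.

### The coefficient-recovery regime

The exponential model family contains the logistic truth only where
prevalence is low (`sigmoid(η) ≈ exp(η)` for `η « 0`). The recovery check
therefore uses intercept −6 with coefficients {1.5, −1.0} on uncorrelated
layers and fits the *un-thinned* presence sample (thinning to one point
per cell deliberately flattens the intensity and would bias coefficients
toward zero). This is a mathematical precondition for identifiability, not
a tuning choice; at moderate prevalence the fitted ratios are biased
toward −1 by saturation, which is expected.

## Numerical choices and degenerate inputs

* Raster nodata is NaN in memory, a sentinel on disk; environmental stacks
  intersect nodata masks on construction.
* Thinning keeps the first point per cell in input order; cells are
  half-open `[x, x+cell)`, row 0 is northernmost, conversions use centers.
* Zero-variance variables: flagged and dropped in screening; skipped (with
  a warning) in feature construction.
* Exact collinearity in VIF returns an infinity sentinel, never raises.
* `0·ln 0 ≡ 0` in entropy-type sums; AICc likelihoods floor probabilities
  at 1e−300 before the log.
* Screening tie-breaks are by variable-name order, making the report
  deterministic given priorities; the default priority is the univariate
  maxent training gain.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the pipeline derives per-stage seeds by
  hashing the stage name with the global seed.

## Problem sizes

Default test-scale problems use 60×60 grids, ~200 presences, 2 000-cell
backgrounds and 10 hinge/threshold knots per variable; the tuning grid at
this scale completes in about a minute, and the recovery study (80×80,
2 000 presences, 10 000 background cells) in a few seconds. These sizes
are the package's defaults for its synthetic studies; real-data studies
would raise the background and knot counts toward the conventional 10 000
cells and 30 knots.

## Known limitations

* Cloglog output, categorical features, sampling-bias grids and
  spatial-block cross-validation partitions are not implemented.
* The environment-space overlap mode is a simplified density comparison,
  not an ecospat-style kernel workflow.
* The reserve objective's shortfall penalty is a documented surrogate for
  Marxan's internal calibration; absolute objective values are therefore
  not comparable to Marxan outputs, though the selection behavior
  (targets dominate when SPF is large; BLM trades compactness against
  cost) is.
* All inputs must share one geographic lat/lon grid; there is no
  reprojection.
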