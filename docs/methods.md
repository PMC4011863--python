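# Methods

This note records the statistical models, the numerical choices behind them,
what the synthetic-data generator does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Trees and covariance matrices

Input trees are rooted chronograms with branch lengths in Myr. Newick
parsing/serialization is delegated to dendropy; trees are forced rooted
(dendropy's MRCA machinery silently deroots unrooted trees, which corrupts
depths). Ultrametricity is checked with a relative tolerance of `1e-6` on
root-to-tip depths — chronograms are ultrametric by construction but their
decimal Newick representations drift. Polytomies and zero-length branches are
accepted; they only affect shared path lengths.

The Brownian covariance `V_ij = s_ij` (shared root-to-MRCA path length) is
built in one postorder sweep and cached per tree. Dropping tips leaves shared
paths unchanged, so per-pair complete-case subsets are taken directly from
the full matrix rather than by pruning.

The OU transform uses the single-optimum form with the root state at the
optimum and variance accumulating from zero,

    V_ij(α) = exp(−2α(T − s_ij)) · (1 − exp(−2α s_ij)) / (2α),

which tends to `s_ij` as `α → 0` and to a diagonal `1/(2α)` for strong pull.
The overall rate σ² is never baked into the matrix; it is concentrated out of
every likelihood analytically. Other OU variants (stationary root,
non-ultrametric generalizations) are deliberately out of scope.

## Single-trait model fitting

For a fixed covariance shape `V(θ)`, the ML mean is the GLS mean and the ML
rate uses the divisor `n`; model selection across BM (2 parameters), lambda
and OU (3 each) therefore compares true maximized likelihoods, and AIC
differences of ≥ 4 count as support against a model. Lambda is profiled on
`[0, 1]` by bounded Brent search (`xatol = 1e-8`) with both endpoints
evaluated explicitly, so boundary estimates are exact. The `[0, 1]` domain
matches the convention of reporting lambda as a signal proportion; the
mathematically admissible upper bound can exceed 1 on some trees but is not
searched.

OU fitting profiles `log α` over `[log(1e-4/T), log(100/T)]` with 10
L-BFGS-B restarts from log-uniform random starts; the restart with minimum
deviance (−2 log L) wins. The restart stream derives deterministically from a
caller seed (default `20140506`) so fits are reproducible. The lower bound
keeps the BM limit reachable; the upper bound is effectively the iid limit.

Constant traits are returned flagged `degenerate` (σ² = 0, infinite
log-likelihood) rather than raising, except in signal estimation where a
constant trait is a hard error (lambda is unidentifiable).

## PGLS

`gls_fixed` whitens with the Cholesky factor of `V` and solves ordinary
least squares in the whitened space. `R²` is defined against the
phylogenetic-mean-only model fitted in the same whitened space, so with
`V = I` every statistic collapses exactly to OLS (asserted to 1e-10 against
statsmodels). Significance uses `F = (n−2)R²/(1−R²)` on `(1, n−2)` df.
Perfect fits report `R² = 1` with the smallest positive p-value rather than
zero, keeping p in `(0, 1]`.

**Lambda profiling: REML by default.** When lambda is estimated jointly with
the regression by plain ML, the plug-in F test is visibly anticonservative at
the sample sizes this kind of family-level analysis actually has: with 16
tips we measure an empirical type-I error near 0.09 (2000 null simulations;
the unbounded `corPagel`/`gls` route in R is far worse). Profiling the
*restricted* likelihood — which adds `log det(XᵀV⁻¹X)` and uses the `n − p`
divisor, the standard small-sample treatment for covariance parameters in
GLS — brings the empirical rate to ≈ 0.065–0.07, and that is the default
(`profile="reml"`). `profile="ml"` is retained for comparison with tools
that profile ML. A residual inflation of one to two points above nominal
remains in either case, because the F test conditions on the estimated
lambda; readers should treat p-values within a factor of ~2 of 0.05 at these
sample sizes with caution. Note the AIC-based single-trait comparisons are
unaffected (they stay ML).

The OU variant of PGLS estimates α from the response trait alone (the
response is the variable whose residual structure the transform is meant to
model and this keeps the two-stage procedure well defined), then runs a
fixed-covariance GLS. No multiple-testing correction is applied anywhere;
batteries report raw p with a 0.05 significance flag, and every row carries
its own complete-case `n` because trait coverage differs (genome size: 8 of
16 species).

## Phylogenetic signal

`pagels_lambda` reuses the single-trait lambda ML fit and adds
likelihood-ratio tests against both boundaries (λ = 0 and λ = 1) using the
50:50 boundary-mixture convention: `p = 0.5 · P(χ²₁ > LR)` for positive LR
and 1 otherwise, recorded in the result's metadata. Near-zero estimates are
reported as-is in scientific notation, never floored.

## Climate summarization

Vetting order: exact coordinate duplicates within species are collapsed
(after rounding to 4 decimal places, ~11 m — "unique locality" needs some
definition and this one is conservative); records flagged outside the
accepted range map are dropped; records with elevation outside the supplied
bounds are dropped, records lacking elevation skip that filter with a logged
note. Every rejection carries a reason code, and a species losing all its
records is an error rather than a silent empty summary.

Summaries are min/max/mean/midpoint per bioclim variable, with
`midpoint = (min + max)/2` exactly. `logQ` uses mean Bio12, max Bio5 and min
Bio6 across the kept records; `logQ2` substitutes mean Bio10/Bio11. Log base
10 by default (the aridity-index literature's convention), natural log behind
a flag. `Q ≤ 0` — possible when `Tmax + Tmin < 0` — is a hard error, never a
NaN: a sign error here silently flips the aridity ranking. Because `Q` is
unit-sensitive, the locality reader requires an explicit temperature unit
declaration (`celsius`, or `worldclim-raw` for rasters storing °C × 10, to
which the 0.1 scale is applied on read).

## Calibration priors

"Mean 5, sd 1" for a fossil-anchored lognormal is interpreted BEAST-style:
real-space mean of the unshifted lognormal and log-space sd, so
`μ_log = ln(mean_real) − sd²/2`. This is the only reading under which the
conventionally printed interval endpoints reproduce, and it is asserted in
the tests. Intervals default to the 5th–95th percentile span — the span such
setups print (commonly labelled "95%" even though it is a 90% central
interval; the quantiles are exposed explicitly so there is no ambiguity in
this package's own output). Rounding to 0.1 Myr happens only at presentation.

## Synthetic data

The generator emulates the study design, not any particular real data set:

- a pure-birth (Yule) tree, crown-conditioned, rescaled to exactly 150 Myr,
  16 tips;
- a planted regression between minimum hatching time and minimum larval
  period: `x` is BM (rate 1 per Myr around 35 d, giving a cross-species sd
  of ~12 d), `y = 2 + 1·x + ε` with residuals drawn under lambda = 0.6 at
  rate 0.6 — chosen once to put the planted pair's strength in the range of
  strongly related developmental traits (expected whitened R² ≈ 0.6) while
  leaving climate pairings null;
- genome size as a linear function of midpoint larval period plus
  high-lambda residuals, masked to 8 of 16 species to exercise complete-case
  logic;
- species-level climate means evolving by BM on the tree (rates set so
  cross-species spreads are realistic: annual precipitation sd ≈ 250 mm,
  temperature extremes sd ≈ 3–4 °C), locality counts uniform on [3, 322],
  within-species dispersion of 60 mm (Bio12) and 1.5 °C (temperatures), and
  planted vetting work (a duplicate coordinate, an out-of-range flag, an
  elevation outlier) for species with ≥ 10 records.

A single master seed fans out through `numpy.random.SeedSequence.spawn` in a
fixed stage order, so outputs are bit-reproducible and stages can be
regenerated independently.

What the generator does *not* emulate: spatial autocorrelation of climate
between neighboring localities (dispersion is iid), measurement error in
trait compilations, within-species covariation between developmental traits
and local climate, and non-Gaussian trait distributions. Passing tests
therefore demonstrate that the estimators and the pipeline behave correctly
under the stated generative models — they are not evidence about any real
species data.

## Problem sizes used in the checks

Chosen as the smallest sizes at which the statistical assertions are stable:
lambda recovery uses 200-tip trees with 50 replicates per signal level;
OU-residual slope recovery uses a 100-tip tree with 100 replicates; type-I
calibration uses 2000 trait replicates on one fixed 16-tip chronogram
(mirroring the single-tree inference setting); the end-to-end power check
uses 200 synthetic studies with the planted effect strengthened to residual
lambda 0.99.

## Known limitations

- Simple regression only; no multiple predictors, phylogenetic
  ANOVA/ANCOVA, or measurement-error models.
- Single-optimum OU only; no multi-optimum or early-burst models.
- The OU transform requires ultrametry; non-ultrametric trees are rejected.
- p-values from plug-in lambda remain mildly anticonservative at very small
  n (see above).
- Nexus input is not parsed; convert to Newick first.
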