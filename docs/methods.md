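# Methods

## The competition model

The package is built around the hyperbolic yield–density relation for plant
stands. For a focal species at emerged density N (plants/m²), stand biomass
is

    Y = N / (b0 + b11·N)            (monoculture)

so per-plant weight w = Y/N = 1/(b0 + b11·N) declines with crowding. The
model has two interpretable limits: 1/b0 (g/plant) is the virtual weight of
an isolated plant, and Y → 1/b11 (g/m²) as N → ∞ — the law of constant final
yield. For a biculture the relation is expanded additively in the companion
density:

    Y1 = N1 / (b0 + b11·N1 + b12·N2)

with b12 (m²/g) the interspecific competition coefficient of species 2 on
species 1. The model assumes the hyperbolic form holds over the fitted
density range, that competitive effects are additive in densities, and that
effects of different companions enter independently.

For a mixture of r species the per-species prediction is assembled from
biculture fits only:

    Y_a = N_a / (b̄_a0 + b̄_aa·N_a + Σ_i b_ai·N_i)

where b̄_a0 and b̄_aa are unweighted means of the focal species' intercept and
intraspecific coefficient over its bicultures with the other mixture members,
and each b_ai comes directly from the (a, i) biculture fit. Higher-order
(indirect) interactions are assumed negligible; the mixture model is never
refitted to polyculture data. A consequence worth knowing: zeroing one
species' density in a 3-species model does *not* recover the 2-species model
of the remaining pair, because the averages run over different biculture
sets. This is intended behaviour and is pinned by a regression test.

## Fitting

Fits are unweighted nonlinear least squares on the biomass scale
(`scipy.optimize.least_squares`), not on the inverse-per-plant-weight scale:
inverting small weights would distort the error variance, and the biomass
scale matches the model statement. Starting values come from the exact
linearization 1/w = b0 + b11·N1 + b12·N2 fitted by OLS; when that yields
non-positive values the fallback is (b0 = median(N/Y), b11 = 1/max(Y),
b12 = b11/2). Coefficients are box-constrained to [1e-9, ∞), convergence
tolerance 1e-10 on the relative objective change, at most 500 function
evaluations. Standard errors are the usual asymptotic Jacobian-based ones.

Data conventions: a biculture fit uses the focal species' monoculture plots
*plus* the pair's biculture plots (the combined response surface), so b0 and
b11 are re-estimated per pair and may differ from the monoculture-only fit.
Plots where the focal species has zero density are dropped (per-plant weight
undefined) and counted. Every plot is one observation — no replicate
weighting, reflecting designs that favour many rate treatments over
replicates. A companion that never appears leaves b12 unidentifiable; the
fit then reduces to the two-parameter model, pins b12 at the floor, and
flags the result.

r² is reported as the squared Pearson correlation of observed vs fitted
biomass after z-scoring each within species, so that species of very
different stature are comparable.

## Indices

Competition coefficients are normalized by the intercept (b11/b0, b12/b0,
m²/plant) to control for plant-size bias before comparing species. Relative
competitive ability RC = b11/b12 is identical whether computed from raw or
normalized coefficients (the intercept cancels); the niche differentiation
index of a pair is the product of its two RCs and is order-invariant. The
competitive hierarchy is operationalized as pairwise wins — species a beats
b when RC of b against a is below 1 (b feels a more than itself) — with
ties broken by mean RC, then code; the full win matrix is always reported so
users can apply a different rule. The bundled reference tables print
normalized coefficients to four decimals, so indices recomputed from them
carry ~0.1–0.5% rounding noise relative to originally published derived
values; test tolerances account for exactly this propagation and no more.

## Validation battery

Observed and predicted biomass are z-scored *independently* (sample SD)
within each group — by species, or by site-year × species for multi-site
data. Independent scaling is what makes the regression slope of observed on
predicted equal the Pearson correlation and r² = slope², and it makes all
four indicators invariant to positive affine rescaling of either vector: the
battery scores pattern agreement within a group, not absolute level. The
bias test is a two-sided t-test of slope ≠ 1 with n−2 df at α = 0.05. When
agreement is numerically perfect (standardized RMSE < 1e-10) the t-statistic
is 0/0 noise and the bias p-value is reported as 1. Success requires
RMSE ≤ rmse_max, slope > 0.5, no detected bias, and r² > 0.5. There is no
established convention for "low RMSE" on the standardized scale; the default
rmse_max = 0.75 is a package choice, configurable, and flagged as a
convention in exported reports. Groups with fewer than three pairs or zero
variance are skipped with a warning.

## Seeding-rate grid and Pareto selection

Candidate mixtures live on a per-species integer grid. The increment is 5%
of the species' maximum rate (1.2 × recommended), truncated to a whole seed —
truncation, not rounding, reproduces the conventional increments 17/13/8/4
seeds/m² for the four default species. Levels run from 0 while
level × increment stays within 1.2 × recommended; a candidate is kept when
3–4 species are nonzero and the sum of exact per-species proportions of the
recommended rates is at most 1.2. Exact fractions (k·inc/rec) are used in
the budget and in outputs, which reproduces published total-proportion
values that rounded per-species proportions would miss.

Under this rule the default grid enumerates **10,432** candidates, fourteen
more than the previously published 10,418 for the same increments and
budget. The discrepancy sits at the budget boundary and none of the natural
rule variants reproduces the published count exactly: normalizing
proportions by the printed rounded maxima (350/262/176/86 seeds/m²) gives
10,419; rounding per-species proportions to two decimals before summing
gives 10,565 (10,244 with a strict inequality); exact 6%-of-recommended
steps give 9,405. The stated rule is implemented as written and the count
reported as computed. Downstream results are robust to the main readings:
the stated rule, the rounded-maximum normalization, and the two-decimal
rounding with a non-strict budget all yield the same 38-member Pareto front
and the same 20-row shortlist. Only aggressively different boundary rules
(a strict two-decimal budget, or admitting candidates whose exact
proportion sum exceeds 1.2 but whose rounded sum does not) move one or two
mixtures at the budget boundary on or off the front.

Each candidate is scored by the assembled mixture model of exactly its
species subset, fed the planned seed densities undiscounted — reproducing
published mixture predictions confirms that convention; germination
discounting is available as an option. Evenness is Pielou's
J = (−Σ p_i ln p_i)/ln S over the candidate's predicted biomass shares
(0·ln 0 = 0). Seed cost is Σ proportion × recommended mass rate ÷
germination × 10 × price/kg — the germination divisor converts live-seed
targets to purchased bulk mass; cost is exactly linear in the densities.

The Pareto front maximizes (total biomass, evenness) under weak dominance
with strictness in at least one objective; objective-space duplicates are
all retained. Cost is deliberately *not* a third objective — it is reported
for the shortlist (front members with evenness > 0.8) so users weigh it
afterwards. The front is computed by an exact vectorized dominance scan;
tests cross-check it against an independent O(n²) brute-force oracle.

## Synthetic data generator

The generator's defaults mirror the emulated trial: 8 monoculture rates ×
4 species, 8 rate combinations × 6 bicultures (both unreplicated, as in
designs that prioritize rate coverage), and 5 polyculture combinations × 5
replicates at replacement rates — 105 plots; the multi-site validation
variant produces 9 site-years × 5 blocks × 5 polycultures = 225 plots.
Emergence is binomial at the seed level with establishment defaulting to the
seed-label germination fractions (0.80/0.85/0.80/0.80). Biomass is the exact
competition-model expectation at the realized densities, times a site-year
scalar, times multiplicative lognormal noise (default σ = 0.1; biomass is
positive and its variance grows with the mean, which an additive Gaussian —
available for sensitivity checks — would not capture).

Generating coefficients default to the bundled reference estimates with one
adjustment: each focal species' intercept and intraspecific coefficient are
harmonized to their mean over that species' bicultures, so that every
stratum lies on a single surface per focal species and the noiseless
pipeline simulate → fit → assemble → predict closes to ≤1e-6 relative error.
Unharmonized (stratum-specific) truth is available; with it the closure
property intentionally does not hold, just as monoculture-only and
biculture re-fits of b0/b11 differ on real data.

What passing synthetic tests shows — and does not. The generator draws
noise i.i.d. per plot and holds coefficients fixed within a trial; real
fields add spatial autocorrelation, block effects, weed pressure,
management × environment shifts in the coefficients themselves, and
measurement error in densities. Parameter-recovery and closure tests
therefore validate the *procedure* (estimator consistency, correct
assembly, correct accounting), not field-scale predictive accuracy.
Reproducing a published multi-site validation success rate (e.g. 25/36
groups) requires the archived field dataset; with `covermix validate` the
same battery runs on any such data supplied in the package's observation
format.

At the default study conditions (16 plots per pair fit, σ = 0.1 lognormal),
the intercept b0 is weakly identified — its sampling distribution is wide
(median absolute error ≈ 30%) though nearly unbiased (|median signed error|
≈ 3%), consistent with the large intercept standard errors reported for
field fits of this model family. Competition coefficients b11 and b12 are
recovered with median absolute error under 10%. Recovery tests assert the
signed-median (bias) criterion per coefficient and the degradation of
absolute error as σ grows.

## Numerical choices and degenerate inputs

- Predictions return exactly 0 at zero density (the model's 0/0 limit).
- Budget comparisons in the grid use a 1e-9 absolute slack so exact-boundary
  sums are kept despite floating-point representation.
- Equal-density monoculture data (rank-deficient design) raise a fit error
  rather than returning an arbitrary point on the ridge.
- Evenness is undefined (error) for fewer than two species or zero total
  biomass; shares of zero contribute nothing (0·ln 0 = 0).
- Densities beyond 1.2 × recommended trigger an extrapolation warning but
  predictions are not blocked.

## Problem sizes

Test and acceptance runs use the generator's native sizes: 105-plot trials,
225-plot validation sets, 200-replicate recovery simulations, and the full
10,432-candidate grid. The complete suite runs in well under a minute on a
single CPU.
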