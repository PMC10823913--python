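# Methods

This note documents the models, the numerical choices, and what the
synthetic test bed does and does not establish.

## Stand summaries

A tree record is (species, dbh in cm, stems·ha⁻¹ weight, optional height).
Stand summaries are basal-area based: `BA = Σ wᵢ·π·dbhᵢ²/40000`,
`Dg = √(Σ wᵢ·dbhᵢ²/Σ wᵢ)` (so `Dg²` is exactly the weighted mean squared
diameter), `BA_b` the broadleaf share of BA. The broadleaf/conifer class
is an explicit species table; an unclassified species raises immediately
rather than being guessed from its name. An empty stand is (0, 0, 0) —
`BA_b = 0` keeps the matching space total. Nested plot designs enter only
through the per-hectare weights (`10000 / component area` for a fully
enumerated tree). Counted-but-unmeasured small-tree classes can be
represented as pseudo-species records at the class midpoint diameter;
they contribute to summaries but are flagged so composition validation
can exclude them (the midpoint convention is this package's choice).

## Area-based prediction models

For BA and Dg the model is `ŷ = a₀ + Σ aᵢxᵢ` over lidar metrics, chosen
to maximise adjusted R² among all subsets of at most `max_vars` (default
6) metrics. The search is exhaustive up to 12 candidate metrics and
greedy-forward beyond; ties break by column order, and the search mode is
recorded on the model object. Three response scales are supported:

* untransformed;
* all-variables log: predictions back-transform as
  `P = e^{a₀}·Πxᵢ^{aᵢ}·e^{v/2}` — without `e^{v/2}` the back-transform
  estimates the conditional median, not the mean;
* Box-Cox on the response, `Y = (y^λ−1)/λ`, with λ maximising the profile
  log-likelihood on [−2, 2] (flat/undefined for a near-constant sample);
  predictions invert as `P = (λŶ+1)^{1/λ}·(1 + v/2·(1−λ)/(λŶ+1)²)`.

`v` is the residual variance on the transformed scale with denominator
`n − p − 1`. λ = 0 is handled as the log limit, where the correction
factor is `1 + v/2`; this agrees with the log-scale factor `e^{v/2}` to
O(v²), and the two paths converge as λ → 0. Predictions falling outside
the Box-Cox domain (`λŶ+1 ≤ 0`) are clamped to zero with a warning.
Among the three scales, the per-variable/stratum choice is the lowest
leave-one-out RMSE, simpler scale on ties.

`BA_b` is fitted as a binomial logit GLM weighted by plot basal area
(the effective binomial total), with both-direction stepwise selection
under the classic AIC (k = 2) starting from the full metric set.
Complete separation falls back to a small-ridge penalised fit.
Predictions are clamped to the open unit interval.

Stratified fitting: one model per stratum with at least `min_plots`
(default 30) plots; smaller strata merge into a pooled fallback which
also backs unknown strata at prediction time. Mapping floors BA at 0 and
Dg at the minimum measurable diameter (default 7.5 cm) because the
downscaling divides by Dg.

## Downscaling

Cells and plots are min–max scaled *jointly* per coordinate so the two
sets share one [0,1]³ space; a constant coordinate maps to 0. Matching is
Euclidean-nearest with ties broken by smallest plot id; a forest-type
constraint filters candidates first and falls back (with a warning) when
no plot of the type exists. Empty plots never enter the pool; cells with
zero predicted BA come out empty.

Diameter correction `α = Dg_cell/Dg_plot` is exact by construction, and
because it is a common factor, the ratio of any two species' quadratic
mean diameters in the transformed list equals the field-plot ratio. The
per-record target basal areas cascade the cell BA through class, species
and tree shares, so they sum to the cell BA exactly; when the cell
demands a class the plot lacks, that class's BA is reallocated to the
available class (logged, and reported per cell) rather than silently
lost — re-matching to a plot containing both classes is available behind
a flag. Integer stem counts come from a Bernoulli draw on the fractional
part of the per-cell weight, which is unbiased (`E[ω_int] = ω/16`).
Records rounded to zero stems are dropped and their basal area reported
in a diagnostics field, not redistributed; consequently the generated
cell BA equals the predicted BA minus exactly the dropped amount. The
final diameters re-solve the basal-area identity at the integer counts,
so each retained row carries its target basal area to machine precision.

Randomness enters only through the rounding. Each cell uses an RNG
substream seeded by (global seed, cellID25), making output independent
of iteration order and reproducible byte for byte.

The cell Dg used later for height prediction is recomputed from the
generated list (not read off the ALS map), keeping the height inputs
consistent with the list after rounding.

## Diameter–height model

`h = 1.3 + (1 + a_site)·α_sp·(1 − e^{−α₁·Dg^{α₂}})·(1 − e^{−β_sp·dbh/Dg})^γ`
with plot/site random effect `a_site ~ N(0, σ_b²)` and heteroscedastic
residuals, sd ∝ (fitted)^θ. The curve passes through breast height as
dbh → 0 and is strictly increasing in dbh; `α_sp` is the species
asymptote (m) scaled by the stand development term, `β_sp` the species
approach rate. The three shipped parameter sets are keyed
bauges/milicz/sneznik; the Snežnik set carries `β_sp` and `γ` flagged as
borrowed from the Bauges fit (only dominant trees had heights there) and
its negative variance power is loaded as printed, not re-derived.

Fitting is two-stage: (1) fixed effects by bounded nonlinear least
squares, iteratively reweighted with θ re-estimated from the slope of
log|residual| on log(fitted); multi-starts over α₁ guard against the
near-flat ridge along which only the product `α_sp·α₁` is identified
(bounds: α_sp ≤ 150 m, α₁ ∈ [10⁻⁴, 1]). Ignoring the zero-mean random
effect at this stage keeps the estimator consistent. (2) Variance
components (σ_b, σ, θ) by marginal Gaussian ML with the fixed effects
held; the multiplicative random effect makes the within-plot covariance
a rank-one update of a diagonal, inverted analytically
(Sherman–Morrison). Starting values: α_sp from the tallest tree per
species, β_sp = 1, γ = 1.4. Species with fewer than 100 height
observations pool into `OtherSp`. The borrowed-parameter scheme fixes any
named parameter groups at donor values and estimates the rest.

Generated trees receive population-level predictions (`a_site = 0`) and
no residual noise by default, so the output dataset is deterministic; a
flag can add varPower noise. How the site effect should act on virtual
trees is genuinely open; the population-level choice is the conservative
one.

## Validation

The whole-workflow LOOCV excludes each plot from the regression fits
(default; a fixed-models mode only removes it from matching) *and* from
the matching pool, predicts its co-located cell, generates the tree list
and compares observed vs generated BA, Dg, BA_b, the stem-weighted 95th
diameter percentile and 50th/95th height percentiles. Weighted quantiles
use the left-continuous inverse of the weighted ECDF (generated side
weighted by stem counts, observed side by per-hectare weights). The
report carries the model-only LOOCV RMSEs computed on the same folds, so
the error added by downscaling is directly readable; on self-consistent
synthetic data the two agree closely because the generated cell attains
the predicted values exactly up to Bernoulli rounding.

Dominant heights: `Hdom_T` is the mean of the six tallest generated
stems (a row with n stems counts n times), `Hdom_ALS` the mean of the
six highest CHM local maxima; with fewer than six, all are averaged, and
maxima below 5 m are discarded. Local maxima are strict over the
8-neighbourhood, so plateaus never count (deterministic). The regression
of `Hdom_T` on `Hdom_ALS` is reported with the caveat that lidar metrics
can correlate with `Hdom_ALS` by construction. Intensity normalisation
is a z-score against a reference acquisition using the population sd
(ddof = 0). Height percentiles interpolate linearly between order
statistics.

## Synthetic landscapes

True (BA, Dg, BA_b) fields are Gaussian-filtered white noise rescaled to
mean/sd (BA 25 ± 7 m²·ha⁻¹, Dg 25 ± 5 cm, defaults of a mid-European
mixed forest), BA_b squashed through a logistic; strata are vertical
bands. Plot tree lists draw diameters from a Weibull (shape 2.3), then
three exact rescalings (class reweighting for BA_b, a common diameter
factor for Dg, a global weight factor for BA) reproduce the target triple
to numerical precision. Metrics are stratum-specific affine functions of
the truth plus Gaussian noise, with sds chosen so plot-level prediction
RMSEs land in the operational area-based range (BA ≈ 4–5 m²·ha⁻¹,
Dg ≈ 3 cm, BA_b ≈ 0.13), plus pure-noise nuisance metrics; everything is
kept positive so log-scale models remain applicable. CHM surrogates place
cones with apexes at tree heights on a lattice spaced so every apex is a
strict maximum (overlap is allowed and flagged when a cell is too
crowded).

What this test bed shows: that the algorithms are correct — exact
attainment, unbiased rounding, consistent estimation, near-zero added
workflow error. What it does not show: performance on real point clouds
(no occlusion, co-registration error, species-dependent reflectance or
non-affine metric/stand relationships), realism of species spatial
pattern, or transferability of strata. Height-recovery simulations use
measurement-scale noise (≈0.5 m residual at 25 m, 5 % site effect, stand
Dg spanning 8–45 cm); with the much larger biological residuals of real
inventories the asymptote/rate parameters are identified only with wider
uncertainty, as the published standard errors show.

## Problem sizes and tolerances

Default test and acceptance runs use 12×12–16×16-cell landscapes with
50–100 plots and ~12 trees per plot, 50 plots × 20 trees for
height-recovery simulations, 10⁵ draws for rounding checks, and 1000
random cells for the exact-attainment sweep — sizes at which every
stochastic check is stable across seeds. Exact identities are asserted at
1e-9 relative tolerance; the Box-Cox λ→0 agreement at 1e-6 with small
fitted values (the gap grows as λ·Ŷ²·e^Ŷ); simulation-based recoveries at
the 10–15 % level their Fisher information supports.

## I/O conventions

Rasters are ESRI ASCII grids; cellID25 runs row-major from the
north-west corner, 25 m cell size enforced for cell-id rasters, NODATA
mapped to NaN. The tree table has exactly the columns
`cellID25, sp, n, dbh, h` with identical rows merged (summed n ≥ 1) and
deterministic ordering; CSV dialect is comma-separated, '.' decimal,
UTF-8, no index. Fitted model sets serialise to YAML with form, metrics,
coefficients, λ and v — enough to reproduce predictions exactly.
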