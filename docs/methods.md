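# Methods

This note records the statistical model, the numerical choices, and
the design decisions behind `arealife`, together with what the
synthetic test bed does and does not establish.

## Denominator estimation

Small-area death rates need person-years of exposure by single age and
sex, which official sources rarely publish. The package reconstructs
them from two sources: census counts by (area, single age, sex) for a
census year, and projections by higher-level unit in 5-year age bands
for the census year and each analysis year.

**PCLM graduation.** Each (unit, sex, period) band series is ungrouped
by a penalized composite link model: latent single-age counts
`mu = exp(eta)` with band totals Poisson-distributed around `C mu`,
fitted by iteratively reweighted penalized scoring (working matrix
`Q_ij = C_ij mu_j / (C mu)_i`, weights `C mu`), with a difference
penalty of order 2 on `eta`. Convergence is declared when the relative
change in `eta` falls below 1e-8 (at most 200 iterations; failure
raises an error carrying the iteration trace). The smoothing weight is
selected by AIC = deviance + 2 * trace(hat matrix) over the grid
10^-2 .. 10^6 (half-decade steps), with one refinement: candidates
whose fitted band totals deviate from the observed totals by more than
0.5% (relative, on nonzero bands) are only used if no faithful
candidate exists. Without this constraint the AIC can drift to
extreme smoothing on very smooth series, washing out small terminal
bands; with it, band fidelity holds at the level the allocation
arithmetic assumes. After fitting, single-age counts are rescaled
within each band so band totals match the input exactly (the default;
`rescale=False` exposes the raw fit).

**Allocation in two stages.** Stage one computes each area's census
share within its unit per (age, sex) and applies it to the graduated
census-year projections, yielding corrected census-year populations by
area and single age. Stage two recomputes shares from those corrected
counts and applies them to the graduated analysis-year projections.
Exposure for the pooled analysis period is the sum of the annual
allocated populations (three mid-year populations for a pooled
triennium). A mid-period population times the period length is the
other common convention; summing annual projections is the default
because it uses all the projection information and the two agree to
within the projections' own year-to-year variation.

Strata whose unit-level census total is zero receive zero population
(flagged `zero_unit`), are excluded from the Poisson likelihood rather
than imputed, and drop the corresponding projection mass. Fractional
populations are retained throughout — denominators feed rates, not
counts. Open-ended terminal ages default to 103 (women) and 100 (men)
and are configurable per sex.

## The standard schedule

TOPALS needs a city-level standard. Pooled city death counts `D_x` and
exposures `N_x` give empirical log rates `log((D_x + 0.5)/N_x)` (the
half-death shift keeps zero-death ages finite and is close to
median-unbiased for small Poisson counts). These are smoothed by a
degree-2 LOESS (tricube weights, span 0.4 of the age range by
default). Two deliberate departures from a plain smooth:

* Ages below 5 keep their empirical rates. The infant limb of the
  schedule decays on a sub-year scale; no polynomial window can track
  it, and including it in the fit contaminates the child-age trough.
  City-level infant death counts are large enough to use directly,
  and the spline offsets have knots at ages 0 and 1 precisely so that
  area-level infant deviations remain estimable.
* Ages with zero city exposure are excluded from the fit and take the
  extrapolated local fit (with a warning).

LOESS robustness iterations (bisquare reweighting) exist as an option
but are off by default: the age pattern of Poisson noise is strongly
heteroskedastic, and residual-based reweighting discards legitimate
high-variance child ages rather than outliers.

At large pooled exposure (tens of millions of person-years) the
smoothed standard tracks the generating schedule to within ~0.1 on the
log scale at ages 5-90. At realistic single-city exposure (~2 million
person-years per sex) child-age sampling noise alone produces log
errors of 0.2-0.4 there; this is a property of the data, not the
smoother, and is absorbed downstream because a standard-schedule error
common to all areas is corrected by the offset field at essentially no
prior cost (the spatial penalty only prices differences between
neighbors).

## The Bayesian TOPALS model

For area a and age x,

    D_ax ~ Poisson(N_ax * m_a(x)),
    log m_a(x) = log m_std(x) + B(x)' alpha_a,

with B the piecewise-linear tent basis over knots {0, 1, 10, 20, 40,
70} (value 1 at its knot, 0 at the adjacent knots, held constant
beyond the boundary knots; rows sum to 1 inside the span). Strata with
zero exposure are excluded from the likelihood.

**Prior.** Offsets are penalized by
`tau_spatial/2 * sum_{a~a'} ||alpha_a - alpha_a'||^2` over adjacent
area pairs (an intrinsic-CAR-type improper prior) plus
`tau_shape/2 * sum_a sum_k (alpha_a[k+1] - alpha_a[k])^2` within each
area. Defaults `tau_spatial = 5`, `tau_shape = 2`. Optionally both
precisions receive Gamma(2, 0.5) priors and are refreshed by conjugate
Gibbs steps (`sample_precisions=True`). No global intercept beyond the
standard and no sum-to-zero constraint on offsets: the likelihood is
informative per area, so the improper prior's free level is absorbed;
this is a configuration point, not a theorem, and is the main reason
the sampler checks acceptance and divergence explicitly. Sexes are
fitted as independent models throughout.

**Sampler.** Per-area offset vectors are updated as blocks by
random-walk Metropolis. Areas are scheduled by greedy graph coloring
of the adjacency graph: all areas in one color class are mutually
non-adjacent, so their full conditionals depend only on the other
classes and an entire class can be proposed, evaluated and
accepted/rejected in one vectorized step — exactly the sequential
blocked sampler, orders of magnitude faster in practice. Proposals are
`alpha_a + scale_a * sd_a * z`: the scalar `scale_a` adapts by
Robbins-Monro toward a 0.3 acceptance rate, and the per-component
`sd_a` is the running posterior standard deviation (Welford updates,
refreshed every 50 iterations from iteration 200). All adaptation
freezes at the end of burn-in, so the retained chain is a fixed
Markov kernel. The sampler retains `(iterations - burn_in) // thin`
draws, records per-area acceptance rates (warning outside
[0.05, 0.95]), raises on a non-finite posterior with a state dump,
and exposes split-chain R-hat and effective sample size via arviz.

Default schedule 10,000 / 8,000 / 1 (2,000 draws) — small enough for
test beds while matching the production draw count; the production
schedule 100,000 / 80,000 / 10 is a parameter choice away.

## Life tables

Rates to life table: `q_x = m_x / (1 + (1 - a_x) m_x)` with
`a_x = 0.5` for x >= 1 and `a_0 = 0.07 + 1.7 m_0` capped to
[0.01, 0.5] (a standard infant-separation approximation; a flat value
can be supplied instead). Radix 100,000; `d = l q`;
`L_x = l_{x+1} + a_x d_x`; the open age is closed with
`L = l / m`; `T` is the reverse cumulative sum of `L` and `e = T / l`.
`q > 1` from extreme MCMC tail rates is clipped to 1 with a warning
rather than raising, so a single wild draw cannot abort a fit. The
whole construction is vectorized over leading axes, so 2,000 draws x
100 areas resolve in one call. Against an independent fine-step
survivorship integration of the piecewise-constant hazard, `e_0`
agrees to well under 0.1 years on realistic schedules; raising the
open age from 100 to 103 moves `e_0` by less than 0.2 years whenever
`m(100) > 0.3`.

Posterior summaries use the median as the point estimate and the
2.5th/97.5th percentiles as the credible interval, with linear
interpolation between order statistics.

## Inequity statistics

* **Gaps:** P90 - P10 and max - min of point-estimate LE across areas,
  per sex; percentiles by linear interpolation.
* **Decile scores:** deciles from linear-interpolation sample
  quantiles; ties sit in the lower decile; decile d scores (d-1)/9.
  Fewer than 10 areas or a constant variable raises.
* **Composite Z-score:** per-variable standardization (n-1
  denominator), unemployment and overcrowding negated, then averaged;
  higher = better conditions.
* **SII:** OLS of LE on the decile score, unweighted, classical
  standard errors, no spatial term — deliberately, because the second
  stage estimates associations, not surfaces. One regression per
  posterior draw; coefficients pooled by Rubin's rules
  (`T = U + (1 + 1/m)B`) with a normal-quantile 95% interval.
  Decile cut points are computed on the pooled (sex-invariant) SES
  values. No multiple-testing adjustment across the five variables,
  which are reported one at a time.

## The synthetic test bed

`simulate_city` generates a rectangular lattice of areas (rook
adjacency) nested in contiguous higher-level units. The generating
schedule is Gompertz-Makeham plus an exponentially decaying infant
term; default parameters give standard life expectancies at birth of
about 82 (women, open age 103) and 77 years (men, open age 100),
matching a middle/high-income urban population. A latent SES field
with exponential spatial correlation (one-step correlation 0.6 by
default) drives both the true offsets (`alpha_a = -0.15 * SES_a` at
every knot, plus spatially correlated knot-level noise of sd 0.05) and
five observed SES variables — noisy logistic transforms calibrated to
plausible census marginals for a high-coverage city (water access
~93-100%, overcrowding ~0.2-3%, unemployment ~3-6%, high-school
completion ~50-90%), with unemployment and overcrowding oriented so
higher raw values mean worse conditions. Populations follow a
stable-population age profile with log-normal area-size variation
around 12,000 residents per area; projections are the true unit
populations grouped into 5-year bands with mild per-unit growth;
deaths are Poisson draws from true rate times true three-year
exposure. Defaults give 100 areas with a few hundred deaths per area
over the pooled period, true P90-P10 LE gaps of 3-4 years, and ranges
of 7-8 years.

What passing tests show: the chain recovers known area-level LE to a
mean absolute error around 0.6 years with ~95% credible-interval
coverage at this data density, graduation reconstructs smooth age
distributions to well under 5% error, and the inequality machinery
recovers generating SES gradients with correct signs and calibrated
intervals. What they do not show: robustness to non-smooth age
distributions (migration spikes), census undercount or georeferencing
loss correlated with SES, cause-of-death structure, or temporal
population dynamics — none of which the generator emulates.

## Problem sizes and runtimes

Defaults are sized so the full suite and the acceptance script each
run in about a minute on one CPU: recovery uses 100 areas with the
10,000 / 8,000 / 1 schedule; the production 100,000-iteration schedule
is exercised on a one-area model for bookkeeping; smoothing accuracy
is certified on a high-exposure city (~4 x 10^7 person-years total)
where the large-sample property genuinely holds; SII interval coverage
uses 200 replicates of 100 areas x 40 draws.

## Known limitations

* The spatial prior's precisions are fixed by default; hyperprior
  sampling is available but adds mixing burden on small graphs.
* Random-walk Metropolis mixes slowly for weakly identified offsets
  (infant knots in low-exposure areas); effective sample sizes there
  can be an order of magnitude below the retained draw count. The
  preconditioned proposals mitigate but do not remove this.
* The LOESS standard is unreliable below age 5 at single-city
  exposure (kept empirical by design); offset knots at 0 and 1 absorb
  the residual level error, which slightly inflates infant-rate
  uncertainty.
* GeoJSON handling is deliberately minimal: rook adjacency from shared
  boundary segments and a property-only choropleth export.
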