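# arealife

Small-area life expectancy estimation for cities: build single-year
population denominators from grouped projections, estimate age- and
sex-specific mortality rates per small area with a Bayesian spatial
TOPALS Poisson model, convert posterior rate draws into single-age life
tables, and quantify spatial inequities in life expectancy (LE) with
gap statistics and slope indices of inequality.

It is aimed at demographers and urban-health researchers who have (a)
death counts by small area, single-year age and sex for a pooled
period, (b) census population counts at single ages, (c) official
population projections in 5-year bands at a coarser administrative
level, and (d) area-level socioeconomic (SES) indicators — the typical
data situation for sub-city mortality analysis in Latin American
cities. A synthetic-city generator with full ground truth makes the
whole chain runnable and testable without any restricted microdata.

## The model

**Denominators.** Projections by higher-level unit come in 5-year age
bands. A penalized composite link model (PCLM) ungroups each band
series into single ages: latent counts are `mu = exp(eta)`, band
totals are Poisson with mean `C mu` for a 0/1 grouping matrix `C`, and
a second-order difference penalty `lambda * ||D2 eta||^2` enforces a
smooth age distribution (`lambda` chosen by AIC over a grid). Unit
counts are then allocated to small areas in proportion to the census
share of each area within its unit at that age and sex, in two stages
(census year first, then the analysis years); exposure is the sum of
the annual allocated populations.

**Mortality.** TOPALS models each area's log mortality as a city
standard plus a linear-spline offset,

    log m_a(x) = log m_std(x) + sum_k B(x, k) alpha_a[k],

with "tent" basis functions B over knot ages {0, 1, 10, 20, 40, 70}.
The standard `m_std` is a degree-2 LOESS smooth of the pooled city
log rates `log((D_x + 0.5) / N_x)`. Deaths are Poisson,
`D_ax ~ Poisson(N_ax m_a(x))`, and the prior on offsets combines an
intrinsic-CAR-style pairwise penalty across adjacent areas
(`tau_spatial / 2 * sum_{a~a'} ||alpha_a - alpha_a'||^2`) with a
within-area first-difference shape penalty. Posterior sampling is
blockwise adaptive random-walk Metropolis (one offset vector per area
per update, scheduled by graph coloring so each sweep is vectorized);
the production schedule of 100,000 iterations with 80,000 burn-in and
thinning by 10 retains 2000 draws.

**Life tables and inequity.** Every retained rate draw becomes a
single-age life table (`q_x = m_x / (1 + (1 - a_x) m_x)`, open age
closed with `L = l / m`), giving 2000 LE values per area at ages 0,
20, 40 and 60; the posterior median is the point estimate and the
2.5th/97.5th percentiles the credible interval. Inequities are
summarized by the P90-P10 and max-min gaps of point-estimate LE
across areas, and by the slope index of inequality (SII): each SES
variable is scored on a 0..1 decile scale (first decile 0, second 1/9,
..., tenth 1), LE is regressed on the score by OLS once per posterior
draw, and the 2000 coefficients are pooled with Rubin's rules
(`T = U + (1 + 1/m) B`). A composite SES Z-score averages the five
standardized indicators with unemployment and overcrowding
sign-reversed, so higher always means better conditions.

## Worked example

```python
import numpy as np
from arealife import (simulate_city, smooth_standard, TopalsMCMC,
                      life_expectancy, summarize_draws, gap_stats, sii_table)
from arealife.pipeline import estimate_denominators

city = simulate_city(n_areas=100, n_units=15, seed=1)
exposure = estimate_denominators(city.census, city.projections, city.units,
                                 city.open_age, 2010, (2015, 2016, 2017))

sex = "F"
deaths = city.deaths_matrix(sex)
N = (exposure[exposure.sex == sex]
     .pivot_table(index="area", columns="age", values="exposure", fill_value=0)
     .reindex(index=city.areas, columns=city.ages(sex), fill_value=0)
     .to_numpy(float))

std = smooth_standard(deaths.sum(0), N.sum(0))
model = TopalsMCMC(iterations=10_000, burn_in=8_000, random_state=1).fit(
    deaths, N, adjacency=city.adjacency, std_log_rate=std.log_rate)

e = life_expectancy(model.rate_draws(), index_ages=(0, 20, 40, 60))
summary = summarize_draws(e, index_ages=(0, 20, 40, 60),
                          areas=city.areas, sex=sex)
print(summary.head(4).round(1).to_string(index=False))
```

```
 area sex  age   le  le_lo  le_hi  n_draws
    0   F    0 84.0   82.7   85.7     2000
    0   F   20 64.7   63.4   66.3     2000
    0   F   40 45.0   43.7   46.6     2000
    0   F   60 25.9   24.8   27.6     2000
```

Area 0's posterior-median LE at birth is 84.0 years with a 95%
credible interval of 82.7-85.7. Across the 100 areas:

```python
e0 = summary.loc[summary.age == 0, "le"].to_numpy()
print({k: round(v, 1) for k, v in gap_stats(e0).items()})
```

```
{'p10': 80.4, 'p90': 83.8, 'p90_p10': 3.4, 'min': 79.4, 'max': 86.0, 'range': 6.5}
```

— a 3.4-year P90-P10 gap in female LE at birth between advantaged and
disadvantaged areas. The pooled slope indices of inequality, one SES
variable at a time:

```python
sii = sii_table(e[..., 0], city.ses, sex=sex)
print(sii[["variable", "pooled_coef", "ci_low", "ci_high"]].round(2).to_string(index=False))
```

```
         variable  pooled_coef  ci_low  ci_high
     water_access         3.54    2.81     4.27
     overcrowding        -3.42   -4.17    -2.66
school_attendance         3.34    2.57     4.11
      high_school         3.49    2.76     4.23
     unemployment        -3.07   -3.88    -2.26
      composite_z         3.42    2.67     4.18
```

Women in areas at the top SES decile (composite Z-score) are estimated
to live 3.4 years longer (95% CI 2.7-4.2) than women in bottom-decile
areas — the generator was built with exactly this kind of SES gradient,
so the sign pattern (positive for education, school attendance, water
access and the composite; negative for overcrowding and unemployment)
is the expected recovery.

The same chain is available from the shell:

```sh
arealife simulate --n-areas 100 --seed 1 --out-dir data/
arealife run --config config.yaml
```

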