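"""Inequality statistics for small-area life expectancy.

Covers the descriptive and regression-based measures used to quantify
spatial inequities:

* P90-P10 and max-min gaps of point-estimate life expectancy across
  areas;
* decile scoring of socioeconomic variables on a 0..1 scale (first
  decile 0, second 1/9, ..., tenth 1);
* a composite SES Z-score: per-variable standardization, sign reversal
  of disadvantage-oriented variables (unemployment, overcrowding), then
  averaging, so higher always means better conditions;
* slope index of inequality (SII): OLS of life expectancy on a decile
  score, repeated per posterior draw and pooled with Rubin's rules, so
  the reported uncertainty carries both sampling (within-draw) and
  posterior (between-draw) variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SES_VARIABLES",
    "REVERSED_VARIABLES",
    "SIIResult",
    "decile_score",
    "composite_z",
    "gap_stats",
    "sii_per_draw",
    "sii_draws",
    "rubin_pool",
    "sii_table",
]

#: canonical SES variable names (percentages at the area level)
SES_VARIABLES = ("water_access", "overcrowding", "school_attendance",
                 "high_school", "unemployment")

#: variables where a higher raw value means worse conditions
REVERSED_VARIABLES = ("overcrowding", "unemployment")


def decile_score(values) -> np.ndarray:
    """Score a variable's areas on a 0..1 decile scale.

    Areas in the first decile score 0, the second 1/9, ..., the tenth 1.
    Decile membership uses linear-interpolation sample quantiles as cut
    points; a value exactly at a cut point stays in the lower decile.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ValueError(f"need at least 10 areas for deciles, got {v.size}")
    if np.all(v == v[0]):
        raise ValueError("all values identical: deciles are undefined")
    cuts = np.quantile(v, np.arange(1, 10) / 10.0)
    decile = 1 + (v[:, None] > cuts[None, :]).sum(axis=1)  # 1..10
    return (decile - 1) / 9.0


def composite_z(ses: pd.DataFrame, variables=SES_VARIABLES,
                reversed_variables=REVERSED_VARIABLES) -> pd.Series:
    """Composite SES Z-score per area.

    Each variable is standardized to mean 0, sd 1 (sample sd, n-1
    denominator); disadvantage-oriented variables are negated; the
    per-area average of the oriented standardized scores is returned.
    Higher = better living conditions.
    """
    if len(ses) < 2:
        raise ValueError("need at least 2 areas")
    cols = []
    for var in variables:
        x = ses[var].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"variable {var!r} has zero variance")
        z = (x - x.mean()) / sd
        if var in reversed_variables:
            z = -z
        cols.append(z)
    return pd.Series(np.mean(cols, axis=0), index=ses.index, name="composite_z")


def gap_stats(le_points) -> dict:
    """P90-P10 and max-min gaps of area-level life expectancy.

    Percentiles use linear interpolation between order statistics.
    """
    v = np.asarray(le_points, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 areas")
    p10, p90 = np.percentile(v, [10, 90])
    return {
        "p10": float(p10),
        "p90": float(p90),
        "p90_p10": float(p90 - p10),
        "min": float(v.min()),
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
    }


def sii_per_draw(le_draw, score) -> tuple[float, float]:
    """OLS slope of life expectancy on a 0..1 decile score, with its
    classical standard error.

    The slope is the slope index of inequality for one posterior draw:
    the modeled difference in life expectancy between areas at score 1
    (top decile) and score 0 (bottom decile).  Plain unweighted OLS
    with no spatial term.
    """
    y = np.asarray(le_draw, dtype=float)
    x = np.asarray(score, dtype=float)
    if y.shape != x.shape:
        raise ValueError("life expectancy and score must be aligned by area")
    if np.all(x == x[0]):
        raise ValueError("constant score: the SII regression is undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr)


def sii_draws(le_draws, score) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`sii_per_draw` over an (n_draws, n_areas) array.

    Closed-form OLS: identical to per-draw ``linregress`` but one pass.
    """
    Y = np.atleast_2d(np.asarray(le_draws, dtype=float))
    x = np.asarray(score, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("constant score: the SII regression is undefined")
    n = x.size
    xc = x - x.mean()
    sxx = np.sum(xc ** 2)
    slopes = (Y @ xc) / sxx
    intercepts = Y.mean(axis=1) - slopes * x.mean()
    resid = Y - intercepts[:, None] - slopes[:, None] * x[None, :]
    s2 = np.sum(resid ** 2, axis=1) / (n - 2)
    ses = np.sqrt(s2 / sxx)
    return slopes, ses


@dataclass
class SIIResult:
    """Rubin-pooled slope index of inequality for one variable/sex."""

    variable: str
    sex: str | None
    pooled_coef: float
    pooled_se: float
    ci_low: float
    ci_high: float
    n_draws: int
    within_var: float
    between_var: float


def rubin_pool(coefs, ses, variable: str = "", sex: str | None = None,
               conf_level: float = 0.95) -> SIIResult:
    """Pool per-draw regression coefficients with Rubin's rules.

    pooled coefficient = mean of the draws' coefficients; total variance
    ``T = U + (1 + 1/m) B`` where U is the mean squared standard error
    (within-draw variance) and B the sample variance of the coefficients
    (between-draw variance).  The confidence interval uses the normal
    quantile on sqrt(T).
    """
    coefs = np.asarray(coefs, dtype=float)
    ses = np.asarray(ses, dtype=float)
    m = coefs.size
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 draws")
    if ses.size != m:
        raise ValueError("coefs and ses must have equal length")
    pooled = float(coefs.mean())
    u_bar = float(np.mean(ses ** 2))
    b = float(coefs.var(ddof=1))
    total = u_bar + (1.0 + 1.0 / m) * b
    se = float(np.sqrt(total))
    zcrit = float(stats.norm.ppf(0.5 + conf_level / 2.0))
    return SIIResult(
        variable=variable, sex=sex, pooled_coef=pooled, pooled_se=se,
        ci_low=pooled - zcrit * se, ci_high=pooled + zcrit * se,
        n_draws=m, within_var=u_bar, between_var=b,
    )


def sii_table(le_draws, ses: pd.DataFrame, sex: str | None = None,
              variables=None, include_composite: bool = True) -> pd.DataFrame:
    """Pooled SII for every SES variable (and the composite Z-score).

    le_draws : (n_draws, n_areas) life expectancy per posterior draw,
        areas ordered as the rows of ``ses``.
    """
    if variables is None:
        variables = [v for v in SES_VARIABLES if v in ses.columns]
    le_draws = np.atleast_2d(np.asarray(le_draws, dtype=float))
    rows = []
    todo = [(v, ses[v].to_numpy(dtype=float)) for v in variables]
    if include_composite:
        todo.append(("composite_z", composite_z(ses).to_numpy()))
    for name, values in todo:
        score = decile_score(values)
        slopes, ses_d = sii_draws(le_draws, score)
        res = rubin_pool(slopes, ses_d, variable=name, sex=sex)
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
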