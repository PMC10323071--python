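"""Single-age period life tables and posterior life-expectancy summaries.

Converts schedules of age-specific central death rates m(x) into the
standard life-table columns (q, l, d, L, T, e) with a closed terminal
age group, and summarizes life expectancy across posterior draws by the
median and a 2.5–97.5 percentile credible interval.

Conventions
-----------
* Ages are integer single years ``0..open_age``; the last age is an
  open-ended interval closed with ``L = l / m``.
* ``a(x)`` (average person-years lived in the interval by those dying in
  it) is 0.5 for ages >= 1.  For infants the default is the separation
  approximation ``a0 = 0.07 + 1.7 * m0`` capped to ``[0.01, 0.5]``; a
  fixed value (e.g. 0.1) may be supplied instead.
* The survivorship radix is 100,000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RADIX",
    "LifeTable",
    "infant_a0",
    "make_life_table",
    "le_at",
    "life_expectancy",
    "summarize_draws",
]

RADIX = 100_000.0

#: index ages reported by default: birth, 20, 40 and 60
DEFAULT_INDEX_AGES = (0, 20, 40, 60)


def infant_a0(m0):
    """Separation factor for age 0 from the infant death rate.

    ``a0 = 0.07 + 1.7 * m0``, capped to [0.01, 0.5].  Light infant
    mortality concentrates deaths early in the first year of life, so
    a0 is well below one half.
    """
    return np.clip(0.07 + 1.7 * np.asarray(m0, dtype=float), 0.01, 0.5)


def _ax_vector(m, a0):
    """a(x) along the last axis of ``m``; a0 may be None (rule) or a float."""
    a = np.full_like(m, 0.5)
    if a0 is None:
        a[..., 0] = infant_a0(m[..., 0])
    else:
        a0 = float(a0)
        if not 0.0 < a0 <= 1.0:
            raise ValueError(f"a0 must lie in (0, 1], got {a0}")
        a[..., 0] = a0
    return a


def _columns(m, a0):
    """Life-table columns for rates ``m`` of shape (..., n_ages).

    Returns dict of arrays with the same leading shape.  Vectorized so
    thousands of posterior draws are processed in one call.
    """
    m = np.asarray(m, dtype=float)
    if m.shape[-1] < 2:
        raise ValueError("need at least two ages (one closed + the open interval)")
    if not np.all(np.isfinite(m)) or np.any(m <= 0):
        raise ValueError("all death rates must be finite and > 0")

    a = _ax_vector(m, a0)
    q = m / (1.0 + (1.0 - a) * m)
    if np.any(q > 1.0):
        warnings.warn("q(x) > 1 produced by extreme rates; clipped to 1", RuntimeWarning)
        q = np.minimum(q, 1.0)
    q[..., -1] = 1.0  # everyone dies in the open interval

    p = 1.0 - q
    # survivors: l(0) = radix, l(x+1) = l(x) * p(x)
    l = np.empty_like(m)
    l[..., 0] = RADIX
    l[..., 1:] = RADIX * np.cumprod(p[..., :-1], axis=-1)
    d = l * q

    L = np.empty_like(m)
    L[..., :-1] = l[..., 1:] + a[..., :-1] * d[..., :-1]
    L[..., -1] = l[..., -1] / m[..., -1]

    T = np.flip(np.cumsum(np.flip(L, axis=-1), axis=-1), axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(l > 0, T / l, 0.0)
    return {"m": m, "a": a, "q": q, "l": l, "d": d, "L": L, "T": T, "e": e}


@dataclass
class LifeTable:
    """A complete single-age life table for one mortality schedule."""

    ages: np.ndarray
    m: np.ndarray
    a: np.ndarray
    q: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray

    @property
    def open_age(self) -> int:
        return int(self.ages[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "mx": self.m,
                "ax": self.a,
                "qx": self.q,
                "lx": self.l,
                "dx": self.d,
                "Lx": self.L,
                "Tx": self.T,
                "ex": self.e,
            }
        )


def make_life_table(m, a0=None, ages=None) -> LifeTable:
    """Build a life table from single-age central death rates.

    Parameters
    ----------
    m : array-like, shape (n_ages,)
        Central death rates for ages 0, 1, ..., open_age.  The last
        entry is the rate of the open-ended terminal group.
    a0 : float, optional
        Infant separation factor.  ``None`` (default) applies the rule
        ``0.07 + 1.7 * m0`` capped to [0.01, 0.5].
    ages : array-like, optional
        Age labels; defaults to ``0..len(m)-1``.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 1:
        raise ValueError("make_life_table takes a single 1-D schedule; "
                         "use life_expectancy for stacked draws")
    if ages is None:
        ages = np.arange(m.size)
    else:
        ages = np.asarray(ages)
        if ages.size != m.size:
            raise ValueError("ages and m must have equal length")
    cols = _columns(m, a0)
    return LifeTable(ages=ages, **cols)


def le_at(table: LifeTable, age: int) -> float:
    """Remaining life expectancy e(x) = T(x)/l(x) at an exact age."""
    idx = np.flatnonzero(table.ages == age)
    if idx.size == 0:
        raise ValueError(f"age {age} not in the life table (open age {table.open_age})")
    return float(table.e[idx[0]])


def life_expectancy(m, index_ages=DEFAULT_INDEX_AGES, a0=None):
    """Life expectancy at the given ages for stacked rate schedules.

    ``m`` has shape (..., n_ages) — e.g. (n_draws, n_areas, n_ages) — and
    the result has shape (..., len(index_ages)).  Ages are 0-based single
    years, so ``index_ages`` double as column indices.
    """
    m = np.asarray(m, dtype=float)
    idx = np.asarray(index_ages, dtype=int)
    if np.any(idx < 0) or np.any(idx >= m.shape[-1]):
        raise ValueError("index ages outside the age range of the schedules")
    cols = _columns(m, a0)
    return cols["e"][..., idx]


def summarize_draws(
    e_draws,
    index_ages=DEFAULT_INDEX_AGES,
    areas=None,
    sex: str | None = None,
) -> pd.DataFrame:
    """Posterior summary of life expectancy across draws.

    Parameters
    ----------
    e_draws : array, shape (n_draws, n_areas, n_index_ages)
        Life expectancies per retained posterior draw (see
        :func:`life_expectancy`).
    index_ages, areas, sex
        Labels for the output table.

    Returns
    -------
    DataFrame with one row per (area, index age): posterior median as
    the point estimate and the 2.5th/97.5th percentiles as the credible
    interval (linear interpolation between order statistics).
    """
    e = np.atleast_3d(np.asarray(e_draws, dtype=float))
    n_draws, n_areas, n_idx = e.shape
    if n_draws < 1:
        raise ValueError("need at least one draw")
    idx = np.asarray(index_ages)
    if idx.size != n_idx:
        raise ValueError("index_ages length does not match draws")
    if areas is None:
        areas = np.arange(n_areas)

    med = np.median(e, axis=0)
    lo, hi = np.percentile(e, [2.5, 97.5], axis=0)
    out = pd.DataFrame(
        {
            "area": np.repeat(np.asarray(areas), n_idx),
            "age": np.tile(idx, n_areas),
            "le": med.ravel(),
            "le_lo": lo.ravel(),
            "le_hi": hi.ravel(),
            "n_draws": n_draws,
        }
    )
    if sex is not None:
        out.insert(1, "sex", sex)
    return out
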