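"""Synthetic cities with known mortality and SES ground truth.

Every downstream stage (graduation, allocation, TOPALS fitting, life
tables, inequality statistics) is tested against parameter recovery on
cities generated here.  A city is a rectangular lattice of small areas
nested in contiguous higher-level units.  Each area's log mortality is
a parametric Gompertz-Makeham standard schedule (with an infant
mortality term) plus a linear-spline offset driven by a spatially
autocorrelated latent SES field: higher SES lowers mortality.  Observed
SES variables are noisy monotone transforms of the latent field, with
unemployment and overcrowding oriented so that higher raw values mean
worse conditions.  Death counts are Poisson draws from true rate times
true person-years of exposure.

Default scale emulates a dense Latin-American city core: 100 areas of
about 12,000 residents in ~15 administrative units, three pooled
analysis years, a few hundred deaths per area — enough signal for
area-level life expectancy with meaningful posterior uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetable import life_expectancy
from .topals import DEFAULT_KNOTS, StandardSchedule, build_basis

__all__ = [
    "GompertzMakehamParams",
    "FEMALE_SCHEDULE",
    "MALE_SCHEDULE",
    "DEFAULT_OPEN_AGE",
    "SyntheticCity",
    "make_standard_schedule",
    "simulate_city",
    "group_population",
]

#: open-ended terminal ages by sex
DEFAULT_OPEN_AGE = {"F": 103, "M": 100}

ANALYSIS_PERIODS = (2015, 2016, 2017)
CENSUS_PERIOD = 2010


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Hazard m(x) = makeham + gompertz_b * exp(gompertz_rate * x)
    + infant * exp(-infant_decay * x).

    The infant term decays to near zero by age 5.  All parameters are
    nonnegative and the resulting hazard must be strictly positive.
    """

    makeham: float = 4e-4
    gompertz_b: float = 2.5e-5
    gompertz_rate: float = 0.1
    infant: float = 3e-3
    infant_decay: float = 1.4
    open_age: int = 100

    def __post_init__(self):
        for name in ("makeham", "gompertz_b", "gompertz_rate",
                     "infant", "infant_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.makeham <= 0 and self.gompertz_b <= 0:
            raise ValueError("hazard would not be strictly positive: "
                             "need makeham > 0 or gompertz_b > 0")


# schedule parameters calibrated so that the standard life expectancy at
# birth is ~82 years for women and ~77 for men, in line with a
# middle/high-income urban population
FEMALE_SCHEDULE = GompertzMakehamParams(
    makeham=1.5e-4, gompertz_b=6.13e-6, gompertz_rate=0.112,
    infant=5e-3, infant_decay=1.4, open_age=103)
MALE_SCHEDULE = GompertzMakehamParams(
    makeham=4.0e-4, gompertz_b=1.63e-5, gompertz_rate=0.105,
    infant=6e-3, infant_decay=1.4, open_age=100)

DEFAULT_SCHEDULES = {"F": FEMALE_SCHEDULE, "M": MALE_SCHEDULE}


def make_standard_schedule(params: GompertzMakehamParams) -> StandardSchedule:
    """Evaluate the parametric hazard on single ages 0..open_age.

    Returns the log schedule (finite everywhere; hazard strictly
    positive by construction).
    """
    ages = np.arange(params.open_age + 1)
    m = (params.makeham
         + params.gompertz_b * np.exp(params.gompertz_rate * ages)
         + params.infant * np.exp(-params.infant_decay * ages))
    if np.any(m <= 0):
        raise ValueError("hazard must be strictly positive at every age")
    return StandardSchedule(ages=ages, log_rate=np.log(m), smoothing_span=0.0)


def _lattice_shape(n_areas: int, grid_shape=None) -> tuple[int, int]:
    if grid_shape is not None:
        r, c = grid_shape
        if r * c != n_areas:
            raise ValueError(f"grid shape {grid_shape} incompatible with "
                             f"{n_areas} areas")
        return int(r), int(c)
    best = None
    for r in range(1, int(np.sqrt(n_areas)) + 1):
        if n_areas % r == 0:
            best = (r, n_areas // r)
    return best


def _rook_edges(rows: int, cols: int) -> np.ndarray:
    """Rook-neighbor edges of a rows x cols lattice, row-major indexing."""
    edges = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                edges.append((i, i + 1))
            if r + 1 < rows:
                edges.append((i, i + cols))
    return np.asarray(edges, dtype=int).reshape(-1, 2)


def _spatial_field(coords: np.ndarray, rho: float, rng) -> np.ndarray:
    """Zero-mean unit-variance Gaussian field with exponential decay of
    correlation over lattice distance (rho = 1-step correlation)."""
    n = coords.shape[0]
    z = rng.standard_normal(n)
    if rho <= 0:
        return z
    if rho >= 1:
        raise ValueError("spatial_rho must be < 1")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cov = rho ** d
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    f = L @ z
    return (f - f.mean()) / f.std()


def _ses_variables(z: np.ndarray, noise: float, rng) -> pd.DataFrame:
    """Observed SES variables as noisy logistic transforms of latent SES.

    Marginals are calibrated to plausible census spreads for a
    high-coverage city (water access ~93-100%, overcrowding ~0.2-3%,
    unemployment ~3-6%, high-school completion ~50-90%).  Unemployment
    and overcrowding increase as latent SES falls.
    """
    def logistic_pct(intercept, slope, noise_sd):
        eta = intercept + slope * z + noise_sd * rng.standard_normal(z.size)
        return 100.0 / (1.0 + np.exp(-eta))

    return pd.DataFrame({
        "water_access": logistic_pct(4.7, 1.65, noise * 1.0),
        "overcrowding": logistic_pct(-4.96, -0.97, noise * 0.7),
        "school_attendance": logistic_pct(2.47, 0.55, noise * 0.5),
        "high_school": logistic_pct(0.98, 0.69, noise * 0.5),
        "unemployment": logistic_pct(-3.15, -0.23, noise * 0.35),
    })


@dataclass
class SyntheticCity:
    """A simulated city with full ground truth.

    deaths/census/projections/ses/units/adjacency mirror the CSV
    schemas the pipeline consumes; true_* fields hold the generating
    quantities for parameter-recovery tests.
    """

    n_areas: int
    grid_shape: tuple[int, int]
    areas: np.ndarray                      # area identifiers 0..n-1
    adjacency: np.ndarray                  # (E, 2) index pairs
    units: pd.DataFrame                    # area, unit
    latent_ses: np.ndarray                 # latent SES field (mean 0, sd 1)
    ses: pd.DataFrame                      # area + 5 observed variables
    true_log_std: dict                     # sex -> log standard schedule
    true_alpha: dict                       # sex -> (n_areas, n_knots) offsets
    true_rates: dict                       # sex -> (n_areas, n_ages)
    true_exposure: dict                    # sex -> (n_areas, n_ages) person-years
    census: pd.DataFrame                   # area, age, sex, count (census year)
    projections: pd.DataFrame              # unit, age_band, sex, period, count
    deaths: pd.DataFrame                   # area, age, sex, deaths
    open_age: dict
    knots: tuple
    seed: int

    def ages(self, sex: str) -> np.ndarray:
        return np.arange(self.open_age[sex] + 1)

    def deaths_matrix(self, sex: str) -> np.ndarray:
        """Deaths as an (n_areas, n_ages) array for one sex."""
        sub = self.deaths[self.deaths["sex"] == sex]
        return (sub.pivot_table(index="area", columns="age", values="deaths",
                                fill_value=0, aggfunc="sum")
                .reindex(index=self.areas, columns=self.ages(sex), fill_value=0)
                .to_numpy(dtype=float))

    def true_life_expectancy(self, sex: str, index_ages=(0, 20, 40, 60)) -> np.ndarray:
        """Ground-truth life expectancy per area from the true rates."""
        return life_expectancy(self.true_rates[sex], index_ages=index_ages)

    def write(self, out_dir):
        """Write the pipeline's input CSVs (see arealife.io)."""
        from . import io as _io
        _io.write_city(self, out_dir)


def simulate_city(n_areas: int = 100, n_units: int = 15,
                  ses_effect: float = 0.15, spatial_rho: float = 0.6,
                  seed: int = 0, *, grid_shape=None,
                  mean_population: float = 12_000.0, pop_sd_log: float = 0.18,
                  offset_noise: float = 0.05, ses_noise: float = 0.3,
                  growth_rate: float = 0.002, schedules=None,
                  open_age=None, knots=DEFAULT_KNOTS) -> SyntheticCity:
    """Simulate a city on a rectangular lattice.

    Parameters
    ----------
    n_areas : number of small areas (>= 4), laid out on a lattice.
    n_units : number of contiguous higher-level units (<= n_areas).
    ses_effect : slope of the true spline offsets on latent SES; a unit
        rise in latent SES lowers log mortality by this much at every
        knot (so areas with better SES live longer).
    spatial_rho : 1-step lattice correlation of the latent fields
        (0 = independent areas, must be < 1).
    seed : RNG seed; identical seeds reproduce the city byte-for-byte.
    mean_population : mean area population (both sexes, census year).
    offset_noise : sd of the spatially correlated knot-level noise
        added to the offsets on top of the SES gradient.
    growth_rate : mean annual per-unit population growth between the
        census year and the analysis years.
    """
    if n_areas < 4:
        raise ValueError("need at least 4 areas")
    if not 1 <= n_units <= n_areas:
        raise ValueError("need 1 <= n_units <= n_areas")
    rows, cols = _lattice_shape(n_areas, grid_shape)
    rng = np.random.default_rng(seed)
    if schedules is None:
        schedules = DEFAULT_SCHEDULES
    if open_age is None:
        open_age = {s: p.open_age for s, p in schedules.items()}
    sexes = sorted(schedules)

    areas = np.arange(n_areas)
    adjacency = _rook_edges(rows, cols)
    unit_of = (areas * n_units) // n_areas  # contiguous row-major blocks
    units = pd.DataFrame({"area": areas, "unit": unit_of})
    coords = np.stack([areas // cols, areas % cols], axis=1).astype(float)

    latent = _spatial_field(coords, spatial_rho, rng)
    ses = _ses_variables(latent, ses_noise, rng)
    ses.insert(0, "area", areas)

    n_knots = len(knots)
    true_log_std, true_alpha, true_rates, true_exposure = {}, {}, {}, {}
    census_rows, proj_rows, death_rows = [], [], []

    # per-unit annual growth factors (shared across sexes)
    growth = 1.0 + rng.normal(growth_rate, 0.003, size=n_units)

    for sex in sexes:
        sched = make_standard_schedule(schedules[sex])
        ages = sched.ages
        n_ages = ages.size
        basis = build_basis(ages, knots)

        knot_noise = np.stack(
            [_spatial_field(coords, spatial_rho, rng) for _ in range(n_knots)],
            axis=1)
        alpha = -ses_effect * latent[:, None] + offset_noise * knot_noise
        log_m = sched.log_rate[None, :] + alpha @ basis.B.T
        rates = np.exp(log_m)

        # census-year population: stable-population age profile with
        # area-level size variation and mild age-profile noise
        m_std = np.exp(sched.log_rate)
        survival = np.exp(-np.concatenate([[0.0], np.cumsum(m_std[:-1])]))
        weights = survival * np.exp(-0.01 * ages)
        sex_frac = 0.52 if sex == "F" else 0.48
        totals = (mean_population * sex_frac
                  * np.exp(rng.normal(0.0, pop_sd_log, size=n_areas)))
        profile = weights[None, :] * np.exp(
            rng.normal(0.0, 0.08, size=(n_areas, n_ages)))
        profile /= profile.sum(axis=1, keepdims=True)
        census_true = totals[:, None] * profile
        census_counts = np.round(census_true).astype(int)

        # true annual populations and pooled exposure for the analysis years
        exposure = np.zeros_like(census_true)
        annual = {}
        for year in ANALYSIS_PERIODS:
            factor = growth[unit_of] ** (year - CENSUS_PERIOD)
            annual[year] = census_true * factor[:, None]
            exposure += annual[year]

        deaths = rng.poisson(exposure * rates)

        true_log_std[sex] = sched.log_rate
        true_alpha[sex] = alpha
        true_rates[sex] = rates
        true_exposure[sex] = exposure

        census_rows.append(pd.DataFrame({
            "area": np.repeat(areas, n_ages),
            "age": np.tile(ages, n_areas),
            "sex": sex,
            "count": census_counts.ravel(),
        }))
        death_rows.append(pd.DataFrame({
            "area": np.repeat(areas, n_ages),
            "age": np.tile(ages, n_areas),
            "sex": sex,
            "deaths": deaths.ravel(),
        }))

        # unit-level banded projections for census + analysis periods
        year_pops = {CENSUS_PERIOD: census_true, **annual}
        for period, pop in year_pops.items():
            unit_pop = np.zeros((n_units, n_ages))
            np.add.at(unit_pop, unit_of, pop)
            single = pd.DataFrame({
                "unit": np.repeat(np.arange(n_units), n_ages),
                "age": np.tile(ages, n_units),
                "sex": sex,
                "count": unit_pop.ravel(),
            })
            grouped = group_population(single, width=5)
            grouped["period"] = period
            proj_rows.append(grouped)

    projections = pd.concat(proj_rows, ignore_index=True)
    projections["count"] = np.round(projections["count"]).astype(int)
    projections = projections[["unit", "age_band", "sex", "period", "count"]]

    return SyntheticCity(
        n_areas=n_areas, grid_shape=(rows, cols), areas=areas,
        adjacency=adjacency, units=units, latent_ses=latent, ses=ses,
        true_log_std=true_log_std, true_alpha=true_alpha,
        true_rates=true_rates, true_exposure=true_exposure,
        census=pd.concat(census_rows, ignore_index=True),
        projections=projections,
        deaths=pd.concat(death_rows, ignore_index=True),
        open_age=dict(open_age), knots=tuple(knots), seed=seed,
    )


def group_population(pop_single: pd.DataFrame, width: int = 5) -> pd.DataFrame:
    """Aggregate single-age counts into ``width``-year bands.

    The final band is open-ended at the maximum age present (e.g. ages
    0..103 with width 5 give bands 0-4, ..., 95-99, 100+).  Band totals
    equal the sum of their constituent single ages exactly.

    pop_single : DataFrame with columns unit (or area), age, sex, count.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    df = pop_single.copy()
    ages = np.sort(df["age"].unique())
    if ages[0] != 0 or np.any(np.diff(ages) != 1):
        raise ValueError("ages must be contiguous from 0")
    max_age = int(ages[-1])
    open_start = (max_age // width) * width
    lo = np.minimum((df["age"] // width) * width, open_start)
    closed = pd.Series(lo).astype(str) + "-" + pd.Series(lo + width - 1).astype(str)
    if max_age == open_start + width - 1:
        # the age span divides evenly; the last band is a full closed band
        label = closed.to_numpy()
    else:
        label = np.where(lo == open_start, f"{open_start}+", closed)
    df["age_band"] = label
    key = [c for c in ("unit", "area") if c in df.columns] + ["age_band", "sex"]
    if "period" in df.columns:
        key.append("period")
    out = df.groupby(key, as_index=False)["count"].sum()
    return out
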