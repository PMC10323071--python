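"""Single-year population denominators from grouped projections.

Small-area death rates need population at single-year ages, but official
projections are typically published only in 5-year bands at a coarser
administrative level.  This module implements the two-step correction:

1. *Graduation*: ungroup banded unit-level projections into single ages
   with a penalized composite link model (PCLM) — a Poisson model whose
   mean is a grouping matrix applied to latent single-age counts, with a
   difference penalty on the latent log-counts enforcing a smooth age
   distribution.
2. *Allocation*: distribute each unit's single-age counts to its small
   areas proportionally to the census share of each area within the
   unit at that age and sex.

Exposure (person-years) for a pooled multi-year analysis period is the
sum of the annual allocated populations.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator

__all__ = [
    "CompositeLinkProblem",
    "PCLMGraduator",
    "PCLMConvergenceError",
    "composition_matrix",
    "pclm_graduate",
    "select_lambda",
    "parse_band",
    "graduate_projections",
    "census_share",
    "allocate",
    "build_exposure",
]

#: default smoothing-weight grid for AIC selection
DEFAULT_LAMBDA_GRID = tuple(10.0 ** np.arange(-2.0, 6.5, 0.5))


class PCLMConvergenceError(RuntimeError):
    """PCLM scoring failed to converge; carries the iteration trace."""

    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


def composition_matrix(n_ages: int, band_edges) -> np.ndarray:
    """0/1 grouping matrix C with C[i, j] = 1 iff age j falls in band i.

    ``band_edges`` are the left edges of each band plus a final right
    edge, e.g. ``[0, 5, 10, 101]`` for bands 0-4, 5-9, 10-100.
    """
    edges = np.asarray(band_edges, dtype=int)
    if edges[0] != 0 or edges[-1] != n_ages:
        raise ValueError("band edges must start at 0 and end at n_ages")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("band edges must be strictly increasing")
    C = np.zeros((edges.size - 1, n_ages))
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        C[i, lo:hi] = 1.0
    return C


@dataclass
class CompositeLinkProblem:
    """A banded-count ungrouping problem.

    grouped_counts : band totals (length n_bands)
    composition    : 0/1 matrix (n_bands, n_ages); every age in exactly one band
    penalty_order  : order of the difference penalty on latent log counts
    lam            : smoothness weight (>= 0); None defers to AIC selection
    """

    grouped_counts: np.ndarray
    composition: np.ndarray
    penalty_order: int = 2
    lam: float | None = None

    def __post_init__(self):
        self.grouped_counts = np.asarray(self.grouped_counts, dtype=float)
        self.composition = np.asarray(self.composition, dtype=float)
        if self.grouped_counts.ndim != 1:
            raise ValueError("grouped_counts must be 1-D")
        if self.composition.shape[0] != self.grouped_counts.size:
            raise ValueError("composition rows must match number of bands")
        if np.any(self.grouped_counts < 0):
            raise ValueError("grouped counts must be nonnegative")
        colsum = self.composition.sum(axis=0)
        if not np.allclose(colsum, 1.0):
            raise ValueError("every latent age must belong to exactly one band")

    @property
    def n_ages(self) -> int:
        return self.composition.shape[1]


class PCLMGraduator(BaseEstimator):
    """Penalized composite link model fitted by penalized Poisson scoring.

    Latent single-age counts are ``mu = exp(eta)``; observed band totals
    are Poisson with mean ``C @ mu``.  A difference penalty of order
    ``penalty_order`` on ``eta`` (weight ``lam``) makes the latent age
    distribution smooth.  ``lam=None`` selects the weight from
    ``lambda_grid`` by AIC = deviance + 2 * effective dimension.

    Parameters
    ----------
    lam : float or None
        Smoothing weight; None triggers AIC grid selection.
    penalty_order : int
        Difference order of the penalty (2 by default).
    lambda_grid : sequence of float
        Candidate weights for AIC selection.
    rescale : bool
        If True (default) the fitted single-age counts are scaled within
        each band so band totals match the observations exactly.
    tol, max_iter : convergence control for the scoring iterations
        (relative change in eta below ``tol``, at most ``max_iter``).

    Attributes
    ----------
    counts_ : fitted single-age counts (rescaled if requested)
    eta_ : latent log-counts at convergence (before rescaling)
    lam_ : the smoothing weight actually used
    aic_, deviance_, edf_ : fit statistics at ``lam_``
    n_iter_ : scoring iterations used
    """

    def __init__(self, lam=None, penalty_order=2, lambda_grid=DEFAULT_LAMBDA_GRID,
                 rescale=True, tol=1e-8, max_iter=200):
        self.lam = lam
        self.penalty_order = penalty_order
        self.lambda_grid = lambda_grid
        self.rescale = rescale
        self.tol = tol
        self.max_iter = max_iter

    # -- core scoring ----------------------------------------------------
    def _solve(self, y, C, lam):
        """Penalized Poisson scoring for one smoothing weight.

        Returns (eta, mu, aic, deviance, edf, n_iter, trace).
        """
        n_bands, n_ages = C.shape
        order = int(self.penalty_order)
        if n_ages < order + 2:
            raise ValueError(f"need at least penalty_order + 2 = {order + 2} latent ages")
        D = np.diff(np.eye(n_ages), n=order, axis=0)
        P = lam * (D.T @ D)

        total = y.sum()
        # flat start at the average latent count
        eta = np.full(n_ages, np.log(max(total / n_ages, 1e-8)))
        trace = []
        for it in range(1, self.max_iter + 1):
            mu = np.exp(eta)
            gamma = C @ mu
            gamma = np.maximum(gamma, 1e-300)
            # composite-link working matrix: d gamma_i / d eta_j = C_ij mu_j
            Q = C * mu[np.newaxis, :] / gamma[:, np.newaxis]
            W = gamma
            z = Q @ eta + (y - gamma) / gamma
            A = (Q.T * W) @ Q + P
            b = (Q.T * W) @ z
            try:
                eta_new = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                A += 1e-10 * np.eye(n_ages)
                eta_new = np.linalg.solve(A, b)
            eta_new = np.clip(eta_new, -40.0, 40.0)
            change = np.max(np.abs(eta_new - eta)) / max(1.0, np.max(np.abs(eta_new)))
            trace.append(change)
            eta = eta_new
            if change < self.tol:
                break
        else:
            raise PCLMConvergenceError(
                f"PCLM scoring did not converge in {self.max_iter} iterations "
                f"(last relative change {trace[-1]:.3e})", trace)

        mu = np.exp(eta)
        gamma = np.maximum(C @ mu, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / gamma), 0.0) - (y - gamma)
        deviance = 2.0 * dev_terms.sum()
        # effective dimension: trace of the hat matrix of the working fit
        Q = C * mu[np.newaxis, :] / gamma[:, np.newaxis]
        QtWQ = (Q.T * gamma) @ Q
        order = int(self.penalty_order)
        Dm = np.diff(np.eye(C.shape[1]), n=order, axis=0)
        H = np.linalg.solve(QtWQ + lam * (Dm.T @ Dm), QtWQ)
        edf = float(np.trace(H))
        aic = deviance + 2.0 * edf
        return eta, mu, aic, deviance, edf, it, trace

    def fit(self, grouped_counts, composition=None):
        """Fit the model.

        Accepts either a :class:`CompositeLinkProblem` or a pair
        (band totals, composition matrix).
        """
        if isinstance(grouped_counts, CompositeLinkProblem):
            prob = grouped_counts
            y, C = prob.grouped_counts, prob.composition
            lam = prob.lam if self.lam is None else self.lam
        else:
            y = np.asarray(grouped_counts, dtype=float)
            C = np.asarray(composition, dtype=float)
            prob = CompositeLinkProblem(y, C, penalty_order=self.penalty_order, lam=self.lam)
            lam = self.lam
        if np.any(y < 0):
            raise ValueError("band totals must be nonnegative")

        if y.sum() == 0:
            warnings.warn("zero-total input: returning all-zero counts", RuntimeWarning)
            self.counts_ = np.zeros(C.shape[1])
            self.eta_ = np.full(C.shape[1], -np.inf)
            self.lam_ = 0.0 if lam is None else float(lam)
            self.aic_ = self.deviance_ = self.edf_ = float("nan")
            self.n_iter_ = 0
            return self

        if lam is None:
            lam = select_lambda(prob, self.lambda_grid,
                                tol=self.tol, max_iter=self.max_iter)
        eta, mu, aic, dev, edf, n_iter, _ = self._solve(y, C, float(lam))

        counts = mu
        if self.rescale:
            fitted_bands = C @ mu
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(fitted_bands > 0, y / fitted_bands, 0.0)
            counts = mu * (C.T @ factor)

        self.counts_ = counts
        self.eta_ = eta
        self.lam_ = float(lam)
        self.aic_ = aic
        self.deviance_ = dev
        self.edf_ = edf
        self.n_iter_ = n_iter
        return self


def pclm_graduate(problem: CompositeLinkProblem, rescale: bool = True) -> np.ndarray:
    """Ungroup band totals into single-age expected counts (see
    :class:`PCLMGraduator`)."""
    est = PCLMGraduator(lam=problem.lam, penalty_order=problem.penalty_order,
                        rescale=rescale)
    return est.fit(problem).counts_


def select_lambda(problem: CompositeLinkProblem, grid=DEFAULT_LAMBDA_GRID,
                  tol=1e-8, max_iter=200, fidelity_tol=0.005) -> float:
    """Pick the smoothing weight minimizing AIC over a grid.

    Candidates whose fitted band totals deviate from the observed
    totals by more than ``fidelity_tol`` (relative, on nonzero bands)
    are disfavored: the AIC minimum is taken among faithful candidates
    when any exist, so heavy smoothing cannot wash out small bands.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("lambda grid must be nonempty and positive")
    helper = PCLMGraduator(penalty_order=problem.penalty_order, tol=tol, max_iter=max_iter)
    y, C = problem.grouped_counts, problem.composition
    pos = y > 0
    best = {True: (None, np.inf), False: (None, np.inf)}
    failures = []
    for lam in grid:
        try:
            _, mu, aic, _, _, _, _ = helper._solve(y, C, float(lam))
        except PCLMConvergenceError as err:
            failures.append((lam, err))
            continue
        rel = np.abs((C @ mu)[pos] - y[pos]) / y[pos]
        faithful = bool(rel.max() <= fidelity_tol) if pos.any() else True
        if aic < best[faithful][1]:
            best[faithful] = (float(lam), aic)
    if best[True][0] is not None:
        return best[True][0]
    if best[False][0] is not None:
        return best[False][0]
    raise PCLMConvergenceError(
        "no candidate smoothing weight converged", failures)


# -- band parsing and per-unit graduation -------------------------------

_BAND_RE = re.compile(r"^(\d+)\s*(?:-\s*(\d+)|\+)$")


def parse_band(band: str) -> tuple[int, int | None]:
    """Parse an age-band label like ``'5-9'`` or ``'100+'``.

    Returns (low, high) with high None for an open-ended band.
    """
    m = _BAND_RE.match(str(band).strip())
    if not m:
        raise ValueError(f"unparseable age band: {band!r}")
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) is not None else None
    return lo, hi


def graduate_projections(projections: pd.DataFrame, open_age: dict[str, int],
                         lam=None, lambda_grid=DEFAULT_LAMBDA_GRID,
                         penalty_order=2) -> pd.DataFrame:
    """Graduate banded projections into single ages per (unit, sex, period).

    Parameters
    ----------
    projections : DataFrame with columns unit, age_band, sex, period, count.
    open_age : mapping sex -> open-ended age (e.g. {'F': 103, 'M': 100}).
        Latent ages run 0..open_age; the open band is collapsed onto its
        terminal ages.
    lam : fixed smoothing weight, or None for per-series AIC selection.

    Returns DataFrame with columns unit, age, sex, period, count.
    """
    required = {"unit", "age_band", "sex", "period", "count"}
    missing = required - set(projections.columns)
    if missing:
        raise ValueError(f"projections missing columns: {sorted(missing)}")
    out = []
    for (unit, sex, period), grp in projections.groupby(["unit", "sex", "period"]):
        omega = open_age[sex]
        n_ages = omega + 1
        bands = sorted((parse_band(b), b) for b in grp["age_band"].unique())
        edges = [lo for (lo, _hi), _ in bands]
        last_lo, last_hi = bands[-1][0]
        if edges[0] != 0:
            raise ValueError(f"bands for unit {unit} do not start at age 0")
        edges.append(n_ages if last_hi is None else last_hi + 1)
        if edges[-1] != n_ages:
            raise ValueError(
                f"bands for unit {unit}/{sex} end at {edges[-1] - 1}, "
                f"expected open age {omega}")
        C = composition_matrix(n_ages, edges)
        totals = (grp.set_index("age_band")["count"]
                  .reindex([b for _, b in bands]).to_numpy(dtype=float))
        prob = CompositeLinkProblem(totals, C, penalty_order=penalty_order, lam=lam)
        counts = PCLMGraduator(lam=lam, lambda_grid=lambda_grid,
                               penalty_order=penalty_order, rescale=True).fit(prob).counts_
        out.append(pd.DataFrame({
            "unit": unit, "age": np.arange(n_ages), "sex": sex,
            "period": period, "count": counts,
        }))
    return pd.concat(out, ignore_index=True)


# -- census shares, allocation, exposure --------------------------------

def census_share(census: pd.DataFrame, units: pd.DataFrame) -> pd.DataFrame:
    """Share of each small area within its unit, per (age, sex).

    census : DataFrame area, age, sex, count.
    units : DataFrame area, unit (each area in exactly one unit).

    Returns DataFrame area, unit, age, sex, share, zero_unit.  Cells in
    a (unit, age, sex) stratum with zero total get share 0 and are
    flagged ``zero_unit=True``.
    """
    dup = units["area"].duplicated()
    if dup.any():
        raise ValueError(f"areas mapped to multiple units: "
                         f"{sorted(units.loc[dup, 'area'].unique())}")
    merged = census.merge(units, on="area", how="left", validate="many_to_one")
    if merged["unit"].isna().any():
        missing = sorted(merged.loc[merged["unit"].isna(), "area"].unique())
        raise ValueError(f"areas with no unit mapping: {missing}")
    totals = merged.groupby(["unit", "age", "sex"])["count"].transform("sum")
    zero = totals == 0
    share = np.where(zero, 0.0, merged["count"] / totals.where(~zero, 1.0))
    out = merged[["area", "unit", "age", "sex"]].copy()
    out["share"] = share
    out["zero_unit"] = zero.to_numpy()
    return out


def allocate(projection_single: pd.DataFrame, shares: pd.DataFrame,
             provenance: str = "graduated_projection") -> pd.DataFrame:
    """Distribute unit-level single-age counts to areas by census shares.

    projection_single : DataFrame unit, age, sex, period, count.
    shares : output of :func:`census_share`.

    Returns DataFrame area, unit, age, sex, period, count, provenance.
    Unit totals are conserved exactly per (age, sex, period) wherever
    the stratum has a nonzero census total.
    """
    proj_keys = projection_single[["unit", "age", "sex"]].drop_duplicates()
    share_keys = shares[["unit", "age", "sex"]].drop_duplicates()
    missing = proj_keys.merge(share_keys, how="left", on=["unit", "age", "sex"],
                              indicator=True)
    missing = missing[missing["_merge"] == "left_only"]
    if len(missing):
        strata = missing[["unit", "age", "sex"]].to_records(index=False).tolist()
        raise ValueError(f"no census shares for projection strata: {strata[:10]}"
                         + (" ..." if len(strata) > 10 else ""))
    merged = shares.merge(projection_single, on=["unit", "age", "sex"], how="inner")
    merged["count"] = merged["share"] * merged["count"]
    out = merged[["area", "unit", "age", "sex", "period", "count"]].copy()
    out["provenance"] = provenance
    return out.sort_values(["area", "sex", "period", "age"], ignore_index=True)


def build_exposure(population: pd.DataFrame, periods) -> pd.DataFrame:
    """Person-years of exposure: sum of annual populations over the periods.

    population : DataFrame area, age, sex, period, count.
    periods : the analysis years to pool.

    Returns DataFrame area, age, sex, exposure.
    """
    periods = list(periods)
    have = set(population["period"].unique())
    missing = [p for p in periods if p not in have]
    if missing:
        raise ValueError(f"missing periods in population estimate: {missing}")
    sub = population[population["period"].isin(periods)]
    out = (sub.groupby(["area", "age", "sex"], as_index=False)["count"].sum()
           .rename(columns={"count": "exposure"}))
    return out
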