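"""Bayesian spatial TOPALS estimation of small-area mortality rates.

TOPALS (Tool for Projecting Age-specific rates using Linear Splines)
models each area's log mortality as a city-wide *standard schedule*
plus a low-dimensional piecewise-linear offset:

    log m_a(x) = log m_std(x) + sum_k B[x, k] * alpha_a[k]

where B is a "tent" B-spline basis over a handful of knot ages and
alpha_a is the area's offset vector.  Death counts are Poisson with
mean exposure * m_a(x).  The prior couples offsets of adjacent areas
through an intrinsic-CAR-style pairwise-difference penalty (precision
``tau_spatial``) and discourages jagged offsets within an area through
a first-difference penalty across knots (precision ``tau_shape``).
Posterior sampling uses per-area blockwise adaptive random-walk
Metropolis; areas are scheduled by graph coloring so a whole color
class (mutually non-adjacent areas) is updated in one vectorized step,
which is exactly the sequential blocked sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator

__all__ = [
    "DEFAULT_KNOTS",
    "StandardSchedule",
    "TopalsBasis",
    "smooth_standard",
    "loess",
    "build_basis",
    "log_posterior",
    "rate_draws",
    "TopalsMCMC",
    "MCMCDivergenceError",
]

#: canonical TOPALS knot ages
DEFAULT_KNOTS = (0, 1, 10, 20, 40, 70)


class MCMCDivergenceError(RuntimeError):
    """Non-finite posterior encountered during sampling; carries state."""

    def __init__(self, message, state):
        super().__init__(message)
        self.state = state


# ---------------------------------------------------------------------
# standard schedule
# ---------------------------------------------------------------------

@dataclass
class StandardSchedule:
    """City-level smoothed log-mortality by single age (one sex)."""

    ages: np.ndarray
    log_rate: np.ndarray
    smoothing_span: float

    def __post_init__(self):
        self.ages = np.asarray(self.ages)
        self.log_rate = np.asarray(self.log_rate, dtype=float)
        if self.ages.shape != self.log_rate.shape:
            raise ValueError("ages and log_rate must have equal length")
        if not np.all(np.isfinite(self.log_rate)):
            raise ValueError("standard schedule must be finite at every age")


def loess(x, y, span=0.3, degree=2, xout=None, robust_iter=0):
    """Local polynomial (LOESS) smoother with tricube weights.

    For each target point the nearest ``ceil(span * n)`` observations
    are fit by weighted least squares with a degree-``degree``
    polynomial; the fit is evaluated at the target.  ``robust_iter``
    rounds of bisquare residual reweighting (off by default) downweight
    gross outliers; leave it off for strongly heteroskedastic noise,
    where legitimate high-variance points would be discarded.
    Reproduces global polynomials up to ``degree`` exactly.  ``xout``
    evaluates the local fits at points other than the observations
    (mild extrapolation at the boundaries uses the nearest local fit
    window).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)

    def smooth_at(targets, robw):
        out = np.empty(targets.size)
        for i, xi in enumerate(targets):
            d = np.abs(x - xi)
            idx = np.argsort(d, kind="stable")[:k]
            h = d[idx].max()
            if h == 0:
                w = np.ones(idx.size)
            else:
                w = (1.0 - np.minimum(d[idx] / h, 1.0) ** 3) ** 3
                w = np.maximum(w, 1e-12)  # keep the boundary point barely in
            w = w * robw[idx]
            t = x[idx] - xi
            X = np.vander(t, degree + 1, increasing=True)
            sw = np.sqrt(np.maximum(w, 1e-12))
            beta, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
            out[i] = beta[0]
        return out

    robw = np.ones(n)
    for _ in range(robust_iter):
        resid = y - smooth_at(x, robw)
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        robw = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    targets = x if xout is None else np.asarray(xout, dtype=float)
    return smooth_at(targets, robw)


def smooth_standard(city_deaths, city_exposure, span=0.4, ages=None,
                    young_cut=5) -> StandardSchedule:
    """Smooth pooled city-level death rates into the TOPALS standard.

    Empirical log rates ``log((D + 0.5) / N)`` (the half-death shift
    keeps zero-death ages finite) are smoothed by a degree-2 LOESS over
    age.  Ages below ``young_cut`` keep their empirical rates: the
    infant-mortality limb decays too steeply for any polynomial window,
    and city-level infant death counts are large enough to use
    directly.  Ages with zero exposure take the LOESS extrapolation.

    Parameters
    ----------
    city_deaths, city_exposure : arrays by single age (one sex).
    span : fraction of ages in each local fit, in (0, 1].
    young_cut : first age included in the LOESS fit (0 smooths all ages).
    """
    D = np.asarray(city_deaths, dtype=float)
    N = np.asarray(city_exposure, dtype=float)
    if D.shape != N.shape:
        raise ValueError("deaths and exposure must be aligned by age")
    if ages is None:
        ages = np.arange(D.size)
    ages_f = np.asarray(ages, dtype=float)
    pos = N > 0
    if not pos.any():
        raise ValueError("city exposure must be positive at some age")
    if not pos.all():
        warnings.warn(
            f"{int((~pos).sum())} ages with zero city exposure excluded from "
            "the standard-schedule fit; smoothed values extrapolated there",
            RuntimeWarning)
    raw = np.full(D.size, np.nan)
    raw[pos] = np.log((D[pos] + 0.5) / N[pos])
    fit = pos & (ages_f >= young_cut)
    if fit.sum() < 5:
        raise ValueError("too few positive-exposure ages to smooth")
    smoothed = loess(ages_f[fit], raw[fit], span=span, degree=2, xout=ages_f)
    young = pos & (ages_f < young_cut)
    smoothed[young] = raw[young]
    return StandardSchedule(ages=ages, log_rate=smoothed, smoothing_span=span)


# ---------------------------------------------------------------------
# linear-spline basis
# ---------------------------------------------------------------------

@dataclass
class TopalsBasis:
    """Piecewise-linear ("tent") basis over knot ages.

    ``B[x, k]`` is 1 at knot k, decays linearly to 0 at the adjacent
    knots, and is held constant beyond the first/last knot.  Rows sum
    to 1 within the knot span.
    """

    knots: np.ndarray
    ages: np.ndarray
    B: np.ndarray

    @property
    def n_knots(self) -> int:
        return self.B.shape[1]


def build_basis(ages, knots=DEFAULT_KNOTS) -> TopalsBasis:
    """Evaluate the tent basis at the given ages."""
    ages = np.asarray(ages, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.size < 2:
        raise ValueError("need at least 2 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    if knots[0] < ages.min() or knots[-1] > ages.max():
        raise ValueError("knots must lie within the age range")
    K = knots.size
    B = np.empty((ages.size, K))
    for k in range(K):
        e_k = np.zeros(K)
        e_k[k] = 1.0
        # np.interp holds the boundary value constant outside the knots
        B[:, k] = np.interp(ages, knots, e_k)
    return TopalsBasis(knots=knots, ages=ages, B=B)


# ---------------------------------------------------------------------
# posterior density and rate assembly
# ---------------------------------------------------------------------

def _pair_array(adjacency, n_areas):
    """Normalize adjacency to an array of unordered index pairs (E, 2)."""
    if adjacency is None:
        return np.empty((0, 2), dtype=int)
    edges = np.asarray(adjacency, dtype=int)
    if edges.size == 0:
        return np.empty((0, 2), dtype=int)
    if edges.ndim != 2 or edges.shape[1] != 2:
        raise ValueError("adjacency must be an (E, 2) array of index pairs")
    if np.any(edges < 0) or np.any(edges >= n_areas):
        raise ValueError("adjacency indices outside the area range")
    if np.any(edges[:, 0] == edges[:, 1]):
        raise ValueError("self-edges are not allowed")
    # deduplicate as unordered pairs
    lo = edges.min(axis=1)
    hi = edges.max(axis=1)
    return np.unique(np.stack([lo, hi], axis=1), axis=0)


def log_posterior(deaths, exposure, basis: TopalsBasis, std_log_rate, alpha,
                  adjacency=None, tau_spatial=5.0, tau_shape=2.0) -> float:
    """Unnormalized log posterior of all offset vectors.

    ``sum_{a,x} [D log(N m) - N m]`` over strata with positive exposure
    (the log D! constant dropped), minus the pairwise spatial penalty
    ``tau_spatial/2 * sum_{a~a'} ||alpha_a - alpha_a'||^2`` and the
    within-area shape penalty
    ``tau_shape/2 * sum_a sum_k (alpha_a[k+1] - alpha_a[k])^2``.
    """
    D = np.asarray(deaths, dtype=float)
    N = np.asarray(exposure, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if not np.all(np.isfinite(alpha)):
        raise ValueError("offsets must be finite")
    n_areas = D.shape[0]
    if alpha.shape != (n_areas, basis.n_knots):
        raise ValueError("alpha must have shape (n_areas, n_knots)")
    logm = std_log_rate[np.newaxis, :] + alpha @ basis.B.T
    mask = N > 0
    mu = N * np.exp(logm)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_terms = D * np.log(np.where(mask, mu, 1.0)) - mu
    ll = ll_terms[mask].sum()

    pairs = _pair_array(adjacency, n_areas)
    pen_sp = 0.0
    if len(pairs):
        diff = alpha[pairs[:, 0]] - alpha[pairs[:, 1]]
        pen_sp = 0.5 * tau_spatial * np.sum(diff ** 2)
    pen_sh = 0.5 * tau_shape * np.sum(np.diff(alpha, axis=1) ** 2)
    return float(ll - pen_sp - pen_sh)


def rate_draws(std_log_rate, basis: TopalsBasis, alpha_draws) -> np.ndarray:
    """Mortality-rate draws ``exp(log m_std + B alpha)``.

    alpha_draws : (n_draws, n_areas, n_knots) or (n_areas, n_knots).
    Returns rates with the knot axis replaced by the age axis.
    """
    alpha = np.asarray(alpha_draws, dtype=float)
    return np.exp(std_log_rate + alpha @ basis.B.T)


# ---------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------

class TopalsMCMC(BaseEstimator):
    """Adaptive blockwise random-walk Metropolis for the TOPALS model.

    One offset vector per area is updated as a block; proposal scales
    adapt per area toward ``target_accept`` during burn-in and are then
    frozen.  Optionally the two penalty precisions get Gamma hyperpriors
    and are refreshed by conjugate Gibbs steps.

    Parameters
    ----------
    knots : knot ages of the linear-spline basis.
    tau_spatial, tau_shape : penalty precisions (fixed values, and the
        initial values when ``sample_precisions`` is on).
    sample_precisions : if True, tau ~ Gamma(shape, rate) hyperpriors
        (``precision_prior``) are sampled by Gibbs updates.
    iterations, burn_in, thin : MCMC schedule; the sampler retains
        exactly ``(iterations - burn_in) // thin`` draws.
    proposal_scale : initial random-walk standard deviation.
    target_accept : adaptation target for the per-area acceptance rate.
    random_state : seed for the sampler's generator.

    Attributes
    ----------
    alpha_draws_ : (n_draws, n_areas, n_knots) retained offset draws.
    tau_draws_ : (n_draws, 2) retained (tau_spatial, tau_shape) draws
        when ``sample_precisions`` is on.
    acceptance_ : per-area acceptance rate after burn-in.
    basis_, std_log_rate_, ages_ : model ingredients kept for rate
        assembly.
    meta_ : sampler bookkeeping (schedule, seed, acceptance summary).
    """

    def __init__(self, knots=DEFAULT_KNOTS, tau_spatial=5.0, tau_shape=2.0,
                 sample_precisions=False, precision_prior=(2.0, 0.5),
                 iterations=10_000, burn_in=8_000, thin=1,
                 proposal_scale=0.1, target_accept=0.3, random_state=None):
        self.knots = knots
        self.tau_spatial = tau_spatial
        self.tau_shape = tau_shape
        self.sample_precisions = sample_precisions
        self.precision_prior = precision_prior
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.proposal_scale = proposal_scale
        self.target_accept = target_accept
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    def _color_classes(self, n_areas, pairs):
        g = nx.Graph()
        g.add_nodes_from(range(n_areas))
        g.add_edges_from(map(tuple, pairs))
        coloring = nx.coloring.greedy_color(g, strategy="largest_first")
        classes = {}
        for node, color in coloring.items():
            classes.setdefault(color, []).append(node)
        return [np.array(sorted(classes[c])) for c in sorted(classes)]

    def fit(self, deaths, exposure, adjacency=None, std_log_rate=None, ages=None):
        """Run the sampler.

        Parameters
        ----------
        deaths, exposure : arrays (n_areas, n_ages); strata with zero
            exposure are excluded from the likelihood.
        adjacency : (E, 2) array of area index pairs (or None for
            spatially independent areas).
        std_log_rate : the standard schedule's log rates (n_ages,).
        ages : age labels; defaults to 0..n_ages-1.
        """
        D = np.asarray(deaths, dtype=float)
        N = np.asarray(exposure, dtype=float)
        if D.ndim == 1:
            D = D[np.newaxis, :]
            N = N[np.newaxis, :]
        if D.shape != N.shape:
            raise ValueError("deaths and exposure must have the same shape")
        if np.any(D < 0) or np.any(N < 0):
            raise ValueError("deaths and exposure must be nonnegative")
        if std_log_rate is None:
            raise ValueError("a standard schedule (std_log_rate) is required")
        std = np.asarray(std_log_rate, dtype=float)
        if std.size != D.shape[1]:
            raise ValueError("standard schedule length must match the age axis")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        n_areas, n_ages = D.shape
        if ages is None:
            ages = np.arange(n_ages)

        basis = build_basis(ages, self.knots)
        B = basis.B
        K = basis.n_knots
        pairs = _pair_array(adjacency, n_areas)
        self.pairs_ = pairs
        rng = np.random.default_rng(self.random_state)

        self.deaths_ = D.copy()
        self.exposure_ = N.copy()
        mask = N > 0
        D = np.where(mask, D, 0.0)
        Ns = np.where(mask, N, 0.0) * np.exp(std)  # N * m_std, so mu = Ns * exp(B alpha)
        DB = D @ B                                  # sum_x D * B[x, k]

        # neighbor structure
        W = sparse.csr_matrix(
            (np.ones(2 * len(pairs)),
             (np.concatenate([pairs[:, 0], pairs[:, 1]]),
              np.concatenate([pairs[:, 1], pairs[:, 0]]))),
            shape=(n_areas, n_areas)) if len(pairs) else sparse.csr_matrix((n_areas, n_areas))
        deg = np.asarray(W.sum(axis=1)).ravel()
        colors = self._color_classes(n_areas, pairs)
        W_rows = [W[idx] for idx in colors]

        def loglik(alpha_rows, rows):
            return ((DB[rows] * alpha_rows).sum(axis=1)
                    - (Ns[rows] * np.exp(alpha_rows @ B.T)).sum(axis=1))

        def shape_pen(alpha_rows):
            return np.sum(np.diff(alpha_rows, axis=1) ** 2, axis=1)

        tau_sp = float(self.tau_spatial)
        tau_sh = float(self.tau_shape)
        a0, b0 = self.precision_prior

        alpha = np.zeros((n_areas, K))
        scale = np.full(n_areas, float(self.proposal_scale))
        cur_ll = np.array([loglik(alpha[[a]], [a])[0] for a in range(n_areas)])
        cur_sh = shape_pen(alpha)

        # Welford accumulators for per-component proposal preconditioning
        run_n = 0
        run_mean = np.zeros((n_areas, K))
        run_m2 = np.zeros((n_areas, K))
        sd_use = np.ones((n_areas, K))

        n_keep = (self.iterations - self.burn_in) // self.thin
        keep_alpha = np.empty((n_keep, n_areas, K))
        keep_tau = np.empty((n_keep, 2)) if self.sample_precisions else None
        acc_count = np.zeros(n_areas)
        kept = 0

        for t in range(1, self.iterations + 1):
            for idx, Wc in zip(colors, W_rows):
                prop = alpha[idx] + scale[idx, None] * sd_use[idx] \
                    * rng.standard_normal((idx.size, K))
                ll_prop = loglik(prop, idx)
                sh_prop = shape_pen(prop)
                d_ll = ll_prop - cur_ll[idx]
                d_sh = sh_prop - cur_sh[idx]
                if len(pairs):
                    nb_sum = Wc @ alpha
                    d_sp = (deg[idx] * ((prop ** 2).sum(axis=1)
                                        - (alpha[idx] ** 2).sum(axis=1))
                            - 2.0 * ((prop - alpha[idx]) * nb_sum).sum(axis=1))
                else:
                    d_sp = 0.0
                log_ratio = d_ll - 0.5 * tau_sp * d_sp - 0.5 * tau_sh * d_sh
                if not np.all(np.isfinite(log_ratio)):
                    raise MCMCDivergenceError(
                        "non-finite posterior during sampling",
                        {"iteration": t, "areas": idx.tolist(),
                         "alpha": alpha.copy(), "proposal": prop})
                accept = np.log(rng.random(idx.size)) < log_ratio
                rows = idx[accept]
                alpha[rows] = prop[accept]
                cur_ll[rows] = ll_prop[accept]
                cur_sh[rows] = sh_prop[accept]
                if t > self.burn_in:
                    acc_count[idx] += accept
                else:
                    # Robbins-Monro adaptation on the log proposal scale
                    gamma = min(0.25, 5.0 / t)
                    p_acc = np.exp(np.minimum(0.0, log_ratio))
                    scale[idx] *= np.exp(gamma * (p_acc - self.target_accept))

            if t <= self.burn_in:
                # per-component posterior-scale estimate (frozen at burn-in)
                run_n += 1
                delta = alpha - run_mean
                run_mean += delta / run_n
                run_m2 += delta * (alpha - run_mean)
                if t >= 200 and t % 50 == 0:
                    sd_use = np.sqrt(run_m2 / run_n) + 1e-3

            if self.sample_precisions:
                if len(pairs):
                    ss_sp = np.sum((alpha[pairs[:, 0]] - alpha[pairs[:, 1]]) ** 2)
                    tau_sp = rng.gamma(a0 + 0.5 * len(pairs) * K,
                                       1.0 / (b0 + 0.5 * ss_sp))
                ss_sh = cur_sh.sum()
                tau_sh = rng.gamma(a0 + 0.5 * n_areas * (K - 1),
                                   1.0 / (b0 + 0.5 * ss_sh))

            if t > self.burn_in and (t - self.burn_in) % self.thin == 0:
                keep_alpha[kept] = alpha
                if keep_tau is not None:
                    keep_tau[kept] = (tau_sp, tau_sh)
                kept += 1

        acc_rate = acc_count / max(self.iterations - self.burn_in, 1)
        if np.any((acc_rate < 0.05) | (acc_rate > 0.95)):
            warnings.warn(
                f"post-adaptation acceptance outside [0.05, 0.95] for "
                f"{int(np.sum((acc_rate < 0.05) | (acc_rate > 0.95)))} areas",
                RuntimeWarning)

        self.alpha_draws_ = keep_alpha
        self.tau_draws_ = keep_tau
        self.acceptance_ = acc_rate
        self.basis_ = basis
        self.std_log_rate_ = std
        self.ages_ = np.asarray(ages)
        self.proposal_scale_ = scale
        self.n_draws_ = n_keep
        self.meta_ = {
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "n_draws": n_keep,
            "seed": self.random_state,
            "n_areas": n_areas,
            "n_edges": int(len(pairs)),
            "acceptance_mean": float(acc_rate.mean()),
            "acceptance_min": float(acc_rate.min()),
            "acceptance_max": float(acc_rate.max()),
            "sample_precisions": bool(self.sample_precisions),
        }
        return self

    def log_posterior(self, alpha) -> float:
        """Log posterior of an offset configuration under the fitted data."""
        if not hasattr(self, "alpha_draws_"):
            raise RuntimeError("call fit first")
        return log_posterior(self.deaths_, self.exposure_, self.basis_,
                             self.std_log_rate_, alpha, adjacency=self.pairs_,
                             tau_spatial=self.tau_spatial, tau_shape=self.tau_shape)

    def rate_draws(self) -> np.ndarray:
        """Posterior mortality-rate draws, shape (n_draws, n_areas, n_ages)."""
        if not hasattr(self, "alpha_draws_"):
            raise RuntimeError("call fit first")
        return rate_draws(self.std_log_rate_, self.basis_, self.alpha_draws_)

    def diagnostics(self) -> dict:
        """Split-chain R-hat and effective sample size over retained draws."""
        if not hasattr(self, "alpha_draws_"):
            raise RuntimeError("call fit first")
        import arviz as az

        # split the single chain in two so split-R-hat is defined
        n = (self.alpha_draws_.shape[0] // 2) * 2
        half = self.alpha_draws_[:n].reshape(
            2, n // 2, *self.alpha_draws_.shape[1:])
        data = az.from_dict(posterior={"alpha": half})
        rhat = az.rhat(data)["alpha"].values
        ess = az.ess(data)["alpha"].values
        return {
            "rhat_max": float(np.nanmax(rhat)),
            "ess_min": float(np.nanmin(ess)),
            "ess_median": float(np.nanmedian(ess)),
        }
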