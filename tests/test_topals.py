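"""Standard-schedule smoothing, spline basis, posterior density, sampler."""

import numpy as np
import pytest

from arealife.topals import (TopalsMCMC, build_basis, loess, log_posterior,
                             rate_draws, smooth_standard)


class TestLoess:
    def test_reproduces_linear_any_span(self):
        x = np.arange(50, dtype=float)
        y = -8.0 + 0.07 * x
        for span in (0.2, 0.5, 1.0):
            assert np.allclose(loess(x, y, span=span), y, atol=1e-9)

    def test_reproduces_quadratic(self):
        x = np.arange(40, dtype=float)
        y = 1.0 - 0.3 * x + 0.01 * x ** 2
        assert np.allclose(loess(x, y, span=0.4), y, atol=1e-8)

    def test_noise_reduction(self, rng):
        x = np.arange(80, dtype=float)
        truth = -7.0 + 0.05 * x
        noisy = truth + rng.normal(0, 0.3, x.size)
        sm = loess(x, noisy, span=0.4)
        assert np.mean((sm - truth) ** 2) < np.mean((noisy - truth) ** 2)

    def test_robust_iterations_resist_outlier(self, rng):
        x = np.arange(60, dtype=float)
        truth = 2.0 + 0.1 * x
        y = truth + rng.normal(0, 0.05, x.size)
        y[30] += 5.0  # gross outlier
        plain = loess(x, y, span=0.4)
        robust = loess(x, y, span=0.4, robust_iter=2)
        assert (np.abs(robust - truth).max()
                < np.abs(plain - truth).max())

    def test_bad_span(self):
        with pytest.raises(ValueError):
            loess(np.arange(10.0), np.arange(10.0), span=1.5)


class TestSmoothStandard:
    def test_exact_loglinear_rates_pass_through(self):
        """Rates exactly log-linear in age: the smoothed schedule equals
        the empirical one (local quadratics reproduce degree <= 2)."""
        ages = np.arange(60)
        N = np.full(60, 1e5)
        m = np.exp(-9.0 + 0.08 * ages)
        D = m * N - 0.5  # so log((D + 0.5)/N) is exactly log m
        out = smooth_standard(D, N, span=0.5)
        assert np.allclose(out.log_rate, np.log(m), atol=1e-8)

    def test_recovers_generator_schedule_at_high_exposure(self):
        """Pooled synthetic-city rates smooth to within 0.1 of the true
        log schedule at ages 5-90 when exposure is large."""
        from arealife.synthetic import simulate_city

        city = simulate_city(n_areas=16, n_units=4, seed=11,
                             mean_population=8e5, ses_effect=0.0,
                             offset_noise=0.0)
        for sex in "FM":
            D = city.deaths_matrix(sex).sum(axis=0)
            N = city.true_exposure[sex].sum(axis=0)
            assert N.sum() > 1e6
            std = smooth_standard(D, N)
            err = np.abs(std.log_rate - city.true_log_std[sex])
            assert err[5:91].max() < 0.1

    def test_smoothing_beats_raw(self, rng):
        ages = np.arange(90)
        true_log = -9.5 + 0.085 * ages
        N = np.full(90, 5e4)
        D = rng.poisson(np.exp(true_log) * N)
        raw = np.log((D + 0.5) / N)
        sm = smooth_standard(D, N).log_rate
        lo = 5  # infant ages kept empirical by design
        assert (np.mean((sm - true_log)[lo:] ** 2)
                < np.mean((raw - true_log)[lo:] ** 2))

    def test_zero_exposure_age_is_extrapolated(self):
        ages = np.arange(30)
        N = np.full(30, 1e4)
        N[-1] = 0.0
        D = np.exp(-5.0) * N
        with pytest.warns(RuntimeWarning, match="zero city exposure"):
            out = smooth_standard(D, N, span=0.6)
        assert np.isfinite(out.log_rate).all()


class TestBasis:
    def test_unit_vectors_at_knots(self):
        basis = build_basis(np.arange(101), (0, 1, 10, 20, 40, 70))
        for k, knot in enumerate((0, 1, 10, 20, 40, 70)):
            row = basis.B[knot]
            expect = np.zeros(6)
            expect[k] = 1.0
            assert np.allclose(row, expect)

    def test_midpoint_splits_evenly(self):
        basis = build_basis(np.arange(101), (0, 1, 10, 20, 40, 70))
        assert basis.B[30, 3] == pytest.approx(0.5)
        assert basis.B[30, 4] == pytest.approx(0.5)

    def test_rows_sum_to_one_and_bounds(self):
        basis = build_basis(np.arange(101), (0, 1, 10, 20, 40, 70))
        assert np.allclose(basis.B.sum(axis=1), 1.0)
        assert basis.B.min() >= 0.0 and basis.B.max() <= 1.0

    def test_extension_beyond_last_knot(self):
        basis = build_basis(np.arange(101), (0, 1, 10, 20, 40, 70))
        assert np.allclose(basis.B[71:, -1], 1.0)
        assert np.allclose(basis.B[71:, :-1], 0.0)

    def test_too_few_knots(self):
        with pytest.raises(ValueError):
            build_basis(np.arange(10), (5,))

    def test_knots_outside_range(self):
        with pytest.raises(ValueError):
            build_basis(np.arange(10), (0, 20))


class TestLogPosterior:
    @staticmethod
    def tiny_model():
        ages = np.arange(3)
        basis = build_basis(ages, (0, 2))
        D = np.array([[2.0, 1.0, 3.0], [1.0, 0.0, 2.0]])
        N = np.array([[100.0, 120.0, 90.0], [80.0, 0.0, 110.0]])
        std = np.array([-4.0, -4.2, -3.9])
        edges = np.array([[0, 1]])
        return D, N, basis, std, edges

    def test_zero_offsets_equal_standard_likelihood(self):
        D, N, basis, std, edges = self.tiny_model()
        alpha = np.zeros((2, 2))
        lp = log_posterior(D, N, basis, std, alpha, adjacency=edges)
        expect = 0.0
        for a in range(2):
            for x in range(3):
                if N[a, x] > 0:
                    mu = N[a, x] * np.exp(std[x])
                    expect += D[a, x] * np.log(mu) - mu
        assert lp == pytest.approx(expect, rel=1e-12)

    def test_hand_expanded_sum(self):
        """Full posterior on a 2-area, 3-age, 2-knot model recomputed by
        explicit loops."""
        D, N, basis, std, edges = self.tiny_model()
        alpha = np.array([[0.3, -0.2], [-0.1, 0.4]])
        tau_sp, tau_sh = 5.0, 2.0
        lp = log_posterior(D, N, basis, std, alpha, adjacency=edges,
                           tau_spatial=tau_sp, tau_shape=tau_sh)
        expect = 0.0
        for a in range(2):
            for x in range(3):
                if N[a, x] > 0:
                    logm = std[x] + sum(basis.B[x, k] * alpha[a, k]
                                        for k in range(2))
                    mu = N[a, x] * np.exp(logm)
                    expect += D[a, x] * np.log(mu) - mu
        expect -= tau_sp / 2.0 * sum((alpha[0, k] - alpha[1, k]) ** 2
                                     for k in range(2))
        expect -= tau_sh / 2.0 * sum((alpha[a, 1] - alpha[a, 0]) ** 2
                                     for a in range(2))
        assert lp == pytest.approx(expect, rel=1e-12)

    def test_shape_penalty_linearity(self):
        D, N, basis, std, edges = self.tiny_model()
        alpha = np.array([[0.5, -0.5], [0.2, 0.1]])
        lp = [log_posterior(D, N, basis, std, alpha, adjacency=edges,
                            tau_shape=t) for t in (0.0, 1.0, 2.0)]
        assert lp[2] - lp[0] == pytest.approx(2 * (lp[1] - lp[0]), rel=1e-9)

    def test_nonfinite_offsets_error(self):
        D, N, basis, std, edges = self.tiny_model()
        alpha = np.array([[np.inf, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            log_posterior(D, N, basis, std, alpha)


class TestRateDraws:
    def test_zero_offset_gives_standard(self):
        basis = build_basis(np.arange(20), (0, 19))
        std = np.linspace(-6, -2, 20)
        out = rate_draws(std, basis, np.zeros((1, 2)))
        assert np.allclose(out[0], np.exp(std))

    def test_monotone_in_offsets(self):
        basis = build_basis(np.arange(30), (0, 10, 29))
        std = np.full(30, -4.0)
        base = rate_draws(std, basis, np.array([[0.0, 0.0, 0.0]]))
        bumped = rate_draws(std, basis, np.array([[0.0, 0.2, 0.0]]))
        support = basis.B[:, 1] > 0
        assert np.all(bumped[0, support] > base[0, support])
        assert np.allclose(bumped[0, ~support], base[0, ~support])

    def test_hand_assembled_linear_predictor(self, rng):
        basis = build_basis(np.arange(10), (0, 4, 9))
        std = rng.normal(-4, 0.5, 10)
        alpha = rng.normal(0, 0.3, (3, 2, 3))  # (draws, areas, knots)
        out = rate_draws(std, basis, alpha)
        d, a = 1, 0
        expect = np.exp(std + basis.B @ alpha[d, a])
        assert np.allclose(out[d, a], expect)


class TestSampler:
    @staticmethod
    def small_fit(**kw):
        rng = np.random.default_rng(7)
        ages = np.arange(40)
        std = -7.0 + 0.06 * ages
        N = np.full((4, 40), 5e3)
        D = rng.poisson(N * np.exp(std))
        edges = np.array([[0, 1], [1, 2], [2, 3]])
        params = dict(knots=(0, 10, 39), iterations=400, burn_in=200,
                      thin=1, random_state=5)
        params.update(kw)
        return TopalsMCMC(**params).fit(D.astype(float), N, adjacency=edges,
                                        std_log_rate=std)

    def test_draw_count_bookkeeping(self):
        m = self.small_fit(iterations=50, burn_in=30, thin=4)
        assert m.alpha_draws_.shape[0] == (50 - 30) // 4 == 5
        single = self.small_fit(iterations=31, burn_in=30, thin=1)
        assert single.alpha_draws_.shape[0] == 1

    def test_seed_reproducibility(self):
        a = self.small_fit(random_state=123)
        b = self.small_fit(random_state=123)
        assert np.array_equal(a.alpha_draws_, b.alpha_draws_)
        c = self.small_fit(random_state=124)
        assert not np.array_equal(a.alpha_draws_, c.alpha_draws_)

    def test_invalid_schedule(self):
        with pytest.raises(ValueError):
            self.small_fit(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            self.small_fit(thin=0)

    def test_single_area_posterior_matches_poisson_mle(self):
        """With one area and huge exposure the posterior mean rate is
        within Monte-Carlo error of the analytic D/N."""
        ages = np.arange(5)
        std = np.full(5, -3.0)
        N = np.full((1, 5), 1e6)
        D = np.round(N * 0.06)  # true rate 0.06, away from the standard
        m = TopalsMCMC(knots=(0, 4), iterations=4000, burn_in=2000,
                       random_state=3).fit(D, N, std_log_rate=std)
        rates = m.rate_draws().mean(axis=0)[0]
        assert np.allclose(rates, 0.06, rtol=0.01)

    def test_spatial_shrinkage_of_empty_area(self):
        """An area with no exposure takes the average of its neighbors'
        offsets (3-area chain, middle area empty)."""
        rng = np.random.default_rng(1)
        ages = np.arange(30)
        std = np.full(30, -4.0)
        N = np.full((3, 30), 2e4)
        N[1] = 0.0
        true_alpha = np.array([0.5, -0.3])
        D = rng.poisson(N * np.exp(std))
        D[0] = rng.poisson(N[0] * np.exp(std + 0.5))
        D[2] = rng.poisson(N[2] * np.exp(std - 0.3))
        edges = np.array([[0, 1], [1, 2]])
        m = TopalsMCMC(knots=(0, 29), iterations=6000, burn_in=3000,
                       random_state=9).fit(
            D.astype(float), N, adjacency=edges, std_log_rate=std)
        post_mean = m.alpha_draws_.mean(axis=0)
        neighbor_avg = 0.5 * (post_mean[0] + post_mean[2])
        assert np.allclose(post_mean[1], neighbor_avg, atol=0.1)
        # flanking areas sit near their generating offsets
        assert np.allclose(post_mean[0], true_alpha[0], atol=0.1)
        assert np.allclose(post_mean[2], true_alpha[1], atol=0.1)

    def test_relabeling_areas_permutes_posteriors(self):
        """Permuting area labels (with the adjacency permuted to match)
        permutes the posterior summaries, up to Monte-Carlo error."""
        rng = np.random.default_rng(4)
        ages = np.arange(40)
        std = -7.0 + 0.06 * ages
        N = np.full((4, 40), 2e4)
        offsets = np.array([0.3, -0.2, 0.1, -0.4])
        D = rng.poisson(N * np.exp(std + offsets[:, None])).astype(float)
        edges = np.array([[0, 1], [1, 2], [2, 3]])
        perm = np.array([2, 0, 3, 1])
        inv = np.argsort(perm)
        base = TopalsMCMC(knots=(0, 39), iterations=3000, burn_in=1500,
                          random_state=11).fit(D, N, adjacency=edges,
                                               std_log_rate=std)
        permuted = TopalsMCMC(knots=(0, 39), iterations=3000, burn_in=1500,
                              random_state=12).fit(
            D[perm], N[perm], adjacency=inv[edges], std_log_rate=std)
        med_base = np.median(base.alpha_draws_, axis=0)
        med_perm = np.median(permuted.alpha_draws_, axis=0)
        assert np.allclose(med_perm, med_base[perm], atol=0.05)

    def test_precision_sampling_runs(self):
        m = self.small_fit(sample_precisions=True)
        assert m.tau_draws_ is not None
        assert np.all(m.tau_draws_ > 0)

    def test_diagnostics_shape(self):
        m = self.small_fit()
        d = m.diagnostics()
        assert set(d) == {"rhat_max", "ess_min", "ess_median"}
        assert d["ess_min"] > 0
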