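"""Gaussian-mixture machinery against independent numerical oracles."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import kstest, norm

from bayesobs.gmm import (
    GaussianMixture1D,
    LossModel,
    expected_loss,
    fit_loss_sd,
    gm_eval,
    gm_moments,
    kl_nongaussianity,
    laplace_approx,
    max_success_probability,
    mixture_mode,
    optimal_target,
    optimality_index,
    posterior_update,
    power_density,
    sample_average_density,
    success_probability,
)

from conftest import random_mixture


class TestMixtureBasics:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GaussianMixture1D([0.5, 0.4], [0, 1], [0.1, 0.1])  # weights don't sum to 1
        with pytest.raises(ValueError):
            GaussianMixture1D([1.0], [0.0], [0.0])  # zero SD
        with pytest.raises(ValueError):
            GaussianMixture1D([0.5, 0.5], [0.0], [0.1, 0.1])  # length mismatch

    def test_cdf_symmetry_and_quantile(self):
        g = GaussianMixture1D([1.0], [0.0], [0.1])
        assert gm_eval(g, 0.0, "cdf") == pytest.approx(0.5)
        bim = GaussianMixture1D([0.5, 0.5], [-1.0, 1.0], [0.1, 0.1])
        assert gm_eval(bim, 0.5, "quantile") == pytest.approx(0.0, abs=1e-10)

    def test_quantile_domain_error(self):
        g = GaussianMixture1D([1.0], [0.0], [0.1])
        for q in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                gm_eval(g, q, "quantile")

    def test_quantile_roundtrip(self, rng):
        gm = random_mixture(rng, 3)
        lo, hi = gm.ppf(0.001), gm.ppf(0.999)
        x = rng.uniform(lo, hi, size=100)
        for xi in x:
            q = gm.cdf(np.asarray([xi]))[0]
            assert abs(gm.ppf(q) - xi) < 1e-9

    def test_moments_single_and_symmetric(self):
        m, v, s, k = gm_moments(GaussianMixture1D([1.0], [0.3], [0.07]))
        assert (m, v, s, k) == pytest.approx((0.3, 0.07**2, 0.0, 0.0))
        sym = GaussianMixture1D([0.5, 0.5], [-0.2, 0.2], [0.05, 0.05])
        assert gm_moments(sym)[2] == pytest.approx(0.0, abs=1e-12)

    def test_moments_match_monte_carlo(self, rng):
        gm = GaussianMixture1D([0.3, 0.7], [-0.1, 0.12], [0.03, 0.09])
        draws = gm.rvs(rng, 4_000_000)
        m, v, s, k = gm_moments(gm)
        n = draws.size
        assert draws.mean() == pytest.approx(m, abs=3 * np.sqrt(v / n))
        assert draws.var() == pytest.approx(v, rel=0.01)
        from scipy.stats import kurtosis, skew

        assert skew(draws) == pytest.approx(s, abs=3 * np.sqrt(6.0 / n) + 0.01)
        assert kurtosis(draws) == pytest.approx(k, abs=3 * np.sqrt(24.0 / n) + 0.03)


class TestPosteriorUpdate:
    def test_linear_weight_rule(self):
        # prior N(0, sigma), likelihood SD sigma -> w = 1/2
        post = posterior_update(GaussianMixture1D([1.0], [0.0], [0.1]), 0.06, 0.1)
        assert post.base.means[0] == pytest.approx(0.03)
        # w = 0.18^2 / (0.18^2 + 0.06^2) = 0.9
        post = posterior_update(GaussianMixture1D([1.0], [0.0], [0.18]), 1.0, 0.06)
        assert post.base.means[0] == pytest.approx(0.9, rel=1e-12)

    def test_matches_pointwise_quadrature(self, rng):
        for _ in range(20):
            gm = random_mixture(rng, 2)
            cue, lik = float(rng.uniform(-0.2, 0.2)), float(rng.uniform(0.03, 0.15))
            post = posterior_update(gm, cue, lik)
            x = np.linspace(-0.8, 0.8, 1601)
            raw = gm.pdf(x) * norm.pdf(cue, loc=x, scale=lik)
            z, _ = integrate.quad(
                lambda t: gm.pdf(np.asarray([t]))[0] * norm.pdf(cue, loc=t, scale=lik),
                -1.5, 1.5, limit=200,
            )
            assert np.max(np.abs(post.base.pdf(x) - raw / z)) < 1e-8
            assert np.exp(post.log_norm) == pytest.approx(z, rel=1e-8)


class TestExpectedLossAndOptimalTarget:
    def test_gaussian_posterior_minimum_at_mean(self, loss):
        post = posterior_update(GaussianMixture1D([1.0], [0.0], [0.1]), 0.08, 0.06)
        m = post.base.means[0]
        grid = np.linspace(m - 0.2, m + 0.2, 4001)
        el = expected_loss(post, grid, loss)
        assert abs(grid[np.argmin(el)] - m) < 1e-4
        assert optimal_target(post, loss) == pytest.approx(m)

    def test_closed_form_equals_quadrature(self, rng, loss):
        for _ in range(20):
            gm = random_mixture(rng, 3)
            post = posterior_update(gm, float(rng.uniform(-0.2, 0.2)), 0.08)
            a = float(rng.uniform(-0.3, 0.3))
            val, _ = integrate.quad(
                lambda x: post.base.pdf(np.asarray([x]))[0]
                * (-np.exp(-((x - a) ** 2) / (2 * loss.loss_sd**2))),
                -2.0, 2.0, limit=400,
            )
            assert expected_loss(post, a, loss) == pytest.approx(val, abs=1e-8)

    def test_flat_loss_limit(self):
        post = posterior_update(GaussianMixture1D([0.5, 0.5], [-0.2, 0.2], [0.05, 0.05]), 0.0, 0.1)
        wide = LossModel(1e3, 0.08)
        grid = np.linspace(-0.5, 0.5, 101)
        el = expected_loss(post, grid, wide)
        assert np.ptp(el) < 1e-6

    def test_symmetric_bimodal_tie_breaks_left(self, loss):
        gm = GaussianMixture1D([0.5, 0.5], [-0.2, 0.2], [0.04, 0.04])
        post = posterior_update(gm, 0.0, 1e9)  # flat likelihood keeps symmetry
        t = optimal_target(post, loss)
        assert t == pytest.approx(-0.2, abs=1e-6)

    def test_agrees_with_grid_search(self, rng, loss):
        for _ in range(30):
            gm = random_mixture(rng, 3)
            post = posterior_update(gm, float(rng.uniform(-0.2, 0.2)), 0.08)
            t = optimal_target(post, loss)
            grid = np.arange(-0.8, 0.8, 1e-5)
            el = expected_loss(post, grid, loss)
            assert abs(t - grid[np.argmin(el)]) < 1e-4


class TestPowerDensity:
    def test_kappa_one_is_posterior(self, rng):
        gm = random_mixture(rng, 3)
        post = posterior_update(gm, 0.05, 0.08)
        d = power_density(post, 1.0)
        assert np.max(np.abs(d.pdf - post.base.pdf(d.x))) < 1e-12

    def test_gaussian_kappa_scales_sd(self):
        post = posterior_update(GaussianMixture1D([1.0], [0.0], [0.1]), 0.1, 0.1)
        d = power_density(post, 4.0)
        sd = np.sqrt(d.var())
        assert sd == pytest.approx(post.base.sds[0] / 2.0, rel=1e-3)

    def test_large_kappa_concentrates_at_map(self):
        gm = GaussianMixture1D([0.45, 0.55], [-0.15, 0.15], [0.05, 0.05])
        post = posterior_update(gm, 0.0, 1e9)
        d = power_density(post, 50.0)
        mode = mixture_mode(post.base)
        s_peak = 0.05 / np.sqrt(50.0)
        mass = np.trapezoid(
            np.where(np.abs(d.x - mode) <= 3 * s_peak, d.pdf, 0.0), dx=d.dx
        )
        assert mass >= 0.99
        assert d.integral() == pytest.approx(1.0, abs=1e-6)


class TestLaplaceApprox:
    def test_gaussian_exact(self):
        post = posterior_update(GaussianMixture1D([1.0], [0.2], [0.07]), 0.1, 0.05)
        la = laplace_approx(post)
        assert la.means[0] == pytest.approx(post.base.means[0])
        assert la.sds[0] == pytest.approx(post.base.sds[0])

    def test_narrower_than_full_posterior(self):
        gm = GaussianMixture1D([0.6, 0.4], [-0.05, 0.2], [0.05, 0.12])
        post = posterior_update(gm, 0.05, 0.1)
        la = laplace_approx(post)
        assert la.sds[0] ** 2 < post.base.moments()[1]

    def test_curvature_matches_finite_differences(self, rng):
        for _ in range(10):
            gm = random_mixture(rng, 3)
            post = posterior_update(gm, float(rng.uniform(-0.1, 0.1)), 0.08)
            la = laplace_approx(post)
            m = la.means[0]
            h = 1e-5
            lp = lambda x: post.base.logpdf(np.asarray([x]))[0]
            d2 = (lp(m + h) - 2 * lp(m) + lp(m - h)) / h**2
            assert -1.0 / la.sds[0] ** 2 == pytest.approx(d2, rel=1e-4)


class TestSampleAverage:
    def test_k1_is_posterior(self, rng):
        gm = random_mixture(rng, 2)
        post = posterior_update(gm, 0.0, 0.1)
        d = sample_average_density(post, 1)
        assert np.max(np.abs(d.pdf - post.base.pdf(d.x))) < 1e-10

    def test_gaussian_integer_k_exact(self):
        post = posterior_update(GaussianMixture1D([1.0], [0.0], [0.12]), 0.1, 0.1)
        d = sample_average_density(post, 4)
        m, s = post.base.means[0], post.base.sds[0]
        assert np.max(np.abs(d.pdf - norm.pdf(d.x, m, s / 2.0))) < 1e-8

    def test_bimodal_k3_matches_simulation(self, rng):
        gm = GaussianMixture1D([0.5, 0.5], [-0.15, 0.15], [0.05, 0.05])
        post = posterior_update(gm, 0.0, 1e9)
        d = sample_average_density(post, 3)
        sims = post.base.rvs(rng, 3 * 10**6).reshape(-1, 3).mean(axis=1)
        cdf_at = lambda v: np.interp(v, d.x, d.cdf_grid())
        stat = kstest(sims, cdf_at).statistic
        assert stat < 0.005

    def test_domain_error(self, rng):
        post = posterior_update(random_mixture(rng, 2), 0.0, 0.1)
        with pytest.raises(ValueError):
            sample_average_density(post, 0.5)


class TestSuccessProbability:
    def test_gaussian_halfwindow_sd(self):
        # posterior SD = window / 2, response at the mean -> 2 Phi(1) - 1
        window = 0.08
        loss = LossModel(fit_loss_sd(window), window)
        sd_post = window / 2.0
        # choose prior/likelihood so the posterior SD is sd_post
        sp = ss = sd_post * np.sqrt(2.0)
        prior = GaussianMixture1D([1.0], [0.0], [sp])
        p = success_probability(prior, 0.0, ss, 0.0, loss)
        assert p == pytest.approx(2 * norm.cdf(1) - 1, rel=1e-12)

    def test_far_response_probability_zero(self, loss):
        prior = GaussianMixture1D([1.0], [0.0], [0.1])
        assert success_probability(prior, 0.0, 0.06, 50.0, loss) == pytest.approx(0.0)

    def test_matches_quadrature(self, rng, loss):
        for _ in range(20):
            gm = random_mixture(rng, 3)
            cue, csd = float(rng.uniform(-0.2, 0.2)), float(rng.uniform(0.04, 0.14))
            r = float(rng.uniform(-0.3, 0.3))
            post = posterior_update(gm, cue, csd).base
            a = loss.window / 2.0
            val, _ = integrate.quad(
                lambda x: post.pdf(np.asarray([x]))[0],
                r - a, r + a, limit=200,
            )
            assert success_probability(gm, cue, csd, r, loss) == pytest.approx(val, abs=1e-8)


class TestOptimalityIndex:
    def test_never_exceeds_one(self, rng, loss):
        for _ in range(200):
            gm = random_mixture(rng, 3)
            cue = float(rng.uniform(-0.2, 0.2))
            r = float(rng.uniform(-0.4, 0.4))
            idx = optimality_index(gm, cue, 0.08, r, loss)
            assert 0.0 <= idx <= 1.0 + 1e-9

    def test_tail_response_near_zero(self, loss):
        gm = GaussianMixture1D([1.0], [0.0], [0.05])
        assert optimality_index(gm, 0.0, 0.06, 2.0, loss) < 1e-6

    def test_optimal_response_attains_one(self, rng, loss):
        for _ in range(10):
            gm = random_mixture(rng, 2)
            cue = float(rng.uniform(-0.1, 0.1))
            pmax = max_success_probability(gm, cue, 0.08, loss)
            # find the optimizer by dense search and check the index there
            grid = np.linspace(-0.6, 0.6, 24001)
            vals = [success_probability(gm, cue, 0.08, r, loss) for r in grid[::40]]
            best = grid[::40][np.argmax(vals)]
            assert optimality_index(gm, cue, 0.08, best, loss) > 0.999


class TestKlNonGaussianity:
    def test_gaussian_posterior_zero(self):
        post = posterior_update(GaussianMixture1D([1.0], [0.0], [0.1]), 0.1, 0.08)
        kl, flag = kl_nongaussianity(post)
        assert kl == pytest.approx(0.0, abs=1e-10)
        assert not flag

    def test_separated_bimodal_flagged(self):
        gm = GaussianMixture1D([0.5, 0.5], [-0.2, 0.2], [0.05, 0.05])
        post = posterior_update(gm, 0.0, 1e9)
        kl, flag = kl_nongaussianity(post)
        assert kl > 0.02
        assert flag

    def test_invariant_to_translation_and_scale(self, rng):
        gm = GaussianMixture1D([0.3, 0.7], [-0.1, 0.1], [0.04, 0.08])
        post = posterior_update(gm, 0.05, 0.08)
        kl0, _ = kl_nongaussianity(post)
        from bayesobs.gmm import PosteriorMixture

        shifted = PosteriorMixture(post.base.shifted(0.37), post.log_norm)
        scaled = PosteriorMixture(post.base.scaled(2.5), post.log_norm)
        assert abs(kl_nongaussianity(shifted)[0] - kl0) < 1e-9
        assert abs(kl_nongaussianity(scaled)[0] - kl0) < 1e-9


class TestMixtureProperties:
    """Invariants over randomly generated mixtures (hypothesis, derandomized)."""

    from hypothesis import given, settings, strategies as st

    @given(
        w1=st.floats(0.05, 0.95),
        m1=st.floats(-0.3, 0.3),
        m2=st.floats(-0.3, 0.3),
        s1=st.floats(0.02, 0.15),
        s2=st.floats(0.02, 0.15),
        c=st.floats(-0.5, 0.5),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_shift_and_moment_consistency(self, w1, m1, m2, s1, s2, c):
        gm = GaussianMixture1D([w1, 1 - w1], [m1, m2], [s1, s2])
        mean, var, skew, kurt = gm_moments(gm)
        # variance decomposition is exact
        assert var == pytest.approx(
            w1 * (s1**2 + m1**2) + (1 - w1) * (s2**2 + m2**2) - mean**2, abs=1e-12
        )
        # translation shifts the mean only
        m2_, v2_, sk2_, k2_ = gm_moments(gm.shifted(c))
        assert m2_ == pytest.approx(mean + c, abs=1e-12)
        assert (v2_, sk2_, k2_) == pytest.approx((var, skew, kurt), abs=1e-9)
        # cdf is monotone and bounded
        xs = np.linspace(min(m1, m2) - 0.5, max(m1, m2) + 0.5, 50)
        cdf = gm.cdf(xs)
        assert np.all(np.diff(cdf) >= -1e-12)
        assert cdf[0] >= 0 and cdf[-1] <= 1


class TestTranslationEquivariance:
    def test_location_outputs_shift(self, rng, loss):
        for _ in range(10):
            gm = random_mixture(rng, 3)
            cue = float(rng.uniform(-0.1, 0.1))
            c = float(rng.uniform(-0.5, 0.5))
            post0 = posterior_update(gm, cue, 0.08)
            post1 = posterior_update(gm.shifted(c), cue + c, 0.08)
            assert optimal_target(post1, loss) - optimal_target(post0, loss) == pytest.approx(
                c, abs=1e-9
            )
            assert post1.base.moments()[0] - post0.base.moments()[0] == pytest.approx(
                c, abs=1e-12
            )

    def test_loss_sd_fit_is_reasonable(self, cfg):
        # fitted width scales with the window and lies between w/4 and w
        sd = fit_loss_sd(cfg.window)
        assert cfg.window / 4 < sd < cfg.window
        assert fit_loss_sd(2 * cfg.window) == pytest.approx(2 * sd, rel=1e-6)
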