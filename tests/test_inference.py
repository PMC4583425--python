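"""EM components, SQUAREM acceleration and posterior computation."""

import numpy as np
import pytest

from msfoot.inference import (
    EMConfig,
    FitResult,
    PriorModel,
    _pack,
    default_init,
    e_step,
    em_iterate,
    fit_flexbg,
    fit_mixture,
    m_step,
    posterior_odds,
    squarem,
    update_prior,
)
from msfoot.likelihoods import BoundParams, UnboundParams
from msfoot.multiscale import build_pyramid_stack
from msfoot.simulate import fixture_params, simulate_dataset


class TestEStep:
    def test_equal_likelihoods_even_prior(self):
        q = e_step(np.array([-5.0]), np.array([-5.0]), np.array([0.5]))
        assert q[0] == pytest.approx(0.5)

    def test_certain_prior_dominates(self):
        q = e_step(np.array([-100.0]), np.array([-1.0]), np.array([1.0]))
        assert q[0] == pytest.approx(1.0)

    def test_bayes_arithmetic(self):
        # likelihood ratio 9 with even prior -> posterior 0.9
        q = e_step(np.array([np.log(9.0)]), np.array([0.0]), np.array([0.5]))
        assert q[0] == pytest.approx(0.9, abs=1e-12)

    def test_double_minus_inf_falls_back_to_prior(self):
        with pytest.warns(UserWarning):
            q = e_step(np.array([-np.inf]), np.array([-np.inf]), np.array([0.3]))
        assert q[0] == pytest.approx(0.3)


class TestUpdatePrior:
    def test_half_posteriors_give_zero_intercept(self):
        prior = update_prior(np.full(50, 0.5))
        assert abs(prior.beta[0]) < 1e-8

    def test_constant_posterior_closed_form(self):
        # intercept-only weighted MLE: logit(mean q)
        prior = update_prior(np.full(200, 0.8))
        assert prior.beta[0] == pytest.approx(np.log(4.0), abs=1e-4)

    def test_perfect_separation_stays_finite_and_monotone(self):
        q = np.r_[np.zeros(30), np.ones(30)]
        f = np.r_[np.linspace(-2, -1, 30), np.linspace(1, 2, 30)]
        prior = update_prior(q, f[:, None])
        assert np.all(np.isfinite(prior.beta))
        zeta = prior.zeta(f[:, None])
        assert np.all(np.diff(zeta[np.argsort(f)]) >= 0)


class TestMStep:
    def test_all_bound_recovers_split_means(self):
        bound, unbound, _ = fixture_params("footprint_strong", S=1)
        data = simulate_dataset(bound, unbound, N=3000, S=1, L=64, mix=1.0, seed=3)
        stack = build_pyramid_stack(data.counts)
        b0, u0, _ = default_init(stack)
        b1, _ = m_step(stack, np.ones(stack.N), b0, u0,
                       EMConfig(inner_maxiter=100))
        for j in range(3):
            np.testing.assert_allclose(b1.p_bar[j], bound.p_bar[j], atol=0.02)

    def test_all_unbound_leaves_bound_untouched(self, footprint_strong_stack):
        stack = footprint_strong_stack
        b0, u0, _ = default_init(stack)
        b1, u1 = m_step(stack, np.zeros(stack.N), b0, u0, EMConfig())
        np.testing.assert_array_equal(b1.alpha, b0.alpha)
        np.testing.assert_array_equal(b1.lambda0_bar, b0.lambda0_bar)
        for a, b in zip(b1.p_bar, b0.p_bar):
            np.testing.assert_array_equal(a, b)
        assert not np.array_equal(u1.lambda0_bar_o, u0.lambda0_bar_o)

    def test_single_site_mean_update_is_its_total(self):
        counts = np.array([[[5, 3]]])  # one site, one replicate, total 8
        stack = build_pyramid_stack(counts)
        b0 = BoundParams(p_bar=[np.array([0.5])], tau=np.array([10.0]),
                         alpha=[2.0], lambda0_bar=[3.0])
        u0 = UnboundParams(alpha_o=[1.0], lambda0_bar_o=[1.0])
        b1, _ = m_step(stack, np.ones(1), b0, u0, EMConfig(inner_maxiter=200))
        assert b1.lambda0_bar[0] == pytest.approx(8.0, rel=1e-3)


class TestEMDriver:
    def test_converges_and_classifies_well_separated_components(self):
        bound, unbound, _ = fixture_params("footprint_strong", S=1)
        bound = BoundParams(p_bar=bound.p_bar, tau=bound.tau,
                            alpha=bound.alpha, lambda0_bar=[40.0])
        unbound = UnboundParams(alpha_o=unbound.alpha_o, lambda0_bar_o=[4.0])
        data = simulate_dataset(bound, unbound, N=600, S=1, L=64, mix=0.5, seed=8)
        stack = build_pyramid_stack(data.counts)
        fit = fit_mixture(stack)
        assert fit.converged
        res = posterior_odds(stack, fit)
        from msfoot.io_eval import compute_auroc

        assert compute_auroc(res.log_posterior_odds, data.z_true) >= 0.95

    def test_init_at_generating_params_is_near_fixed_point(self):
        bound, unbound, _ = fixture_params("footprint_strong", S=1)
        data = simulate_dataset(bound, unbound, N=2000, S=1, L=64, mix=0.4, seed=5)
        stack = build_pyramid_stack(data.counts)
        prior = PriorModel(beta=np.array([np.log(0.4 / 0.6)]))
        fit = em_iterate(stack, None, (bound, unbound, prior),
                         EMConfig(accelerate=False, max_iter=3))
        traj = fit.loglik_trajectory
        assert abs(traj[1] - traj[0]) < 1e-3 * abs(traj[0])

    def test_one_component_data_degenerates_gracefully(self):
        bound, unbound, _ = fixture_params("footprint_strong", S=1)
        data = simulate_dataset(bound, unbound, N=400, S=1, L=64, mix=0.0, seed=2)
        fit = fit_mixture(build_pyramid_stack(data.counts),
                          config=EMConfig(anchor_bound=False))
        from scipy.special import expit

        assert expit(fit.prior.beta[0]) < 0.2  # zeta collapses toward zero

    def test_monotone_trajectory_on_fixture(self, footprint_strong_stack):
        fit = fit_mixture(footprint_strong_stack)
        assert np.all(np.diff(fit.loglik_trajectory) >= -1e-8)

    def test_replicate_permutation_leaves_shared_params(self, footprint_strong_small):
        counts = footprint_strong_small.counts
        fit_a = fit_mixture(build_pyramid_stack(counts))
        fit_b = fit_mixture(build_pyramid_stack(counts[:, ::-1, :]))
        for j in range(3):
            np.testing.assert_allclose(fit_a.bound.p_bar[j], fit_b.bound.p_bar[j],
                                       atol=1e-3)
        np.testing.assert_allclose(fit_a.bound.lambda0_bar,
                                   fit_b.bound.lambda0_bar[::-1], rtol=1e-3)


class TestSquarem:
    def test_toy_contraction_beats_plain_iteration(self):
        # linear fixed-point map x -> A x + b, spectral radius ~0.97
        rng = np.random.default_rng(0)
        Q = np.linalg.qr(rng.normal(size=(6, 6)))[0]
        A = Q @ np.diag(np.linspace(0.5, 0.97, 6)) @ Q.T
        b = rng.normal(size=6)
        F = lambda x: A @ x + b
        x_star = np.linalg.solve(np.eye(6) - A, b)
        res = squarem(F, np.zeros(6), tol=1e-12, max_iter=200)
        assert np.linalg.norm(res.x - x_star) < 1e-8
        # plain iteration cost to the same accuracy
        x, n_plain = np.zeros(6), 0
        while np.linalg.norm(x - x_star) >= 1e-8:
            x, n_plain = F(x), n_plain + 1
        assert res.n_map_evaluations < n_plain

    def test_forced_plain_step_reproduces_em(self, footprint_strong_stack):
        # steplength -1 is the plain EM step by construction; a SQUAREM run
        # whose extrapolation is disabled must match plain EM's trajectory
        stack = footprint_strong_stack
        init = default_init(stack)
        theta = _pack(*init, False)
        from msfoot.inference import _em_cycle, _unpack

        cfg = EMConfig()
        for _ in range(3):
            b, u, p = _unpack(theta, init, False)
            b, u, p = _em_cycle(stack, None, b, u, p, cfg)
            theta = _pack(b, u, p, False)
        b, u, p = _unpack(theta, init, False)
        # three plain cycles through the packed map land exactly where three
        # EM iterations do
        fit_em = em_iterate(stack, None, init, EMConfig(accelerate=False, max_iter=3))
        np.testing.assert_allclose(b.lambda0_bar, fit_em.bound.lambda0_bar,
                                   rtol=1e-9)

    def test_agrees_with_plain_em_on_data(self, footprint_strong_stack):
        stack = footprint_strong_stack
        init = default_init(stack)
        fit_em = em_iterate(stack, None, init,
                            EMConfig(accelerate=False, tol=1e-11, max_iter=800))
        fit_sq = fit_mixture(stack, init=init,
                             config=EMConfig(tol=1e-11, max_iter=800))
        te = _pack(fit_em.bound, fit_em.unbound, fit_em.prior, False)
        ts = _pack(fit_sq.bound, fit_sq.unbound, fit_sq.prior, False)
        assert np.abs(te - ts).max() < 1e-3
        assert fit_sq.loglik_trajectory[-1] >= fit_em.loglik_trajectory[-1] - 1e-6


class TestFlexbg:
    def test_uniform_naked_dna_recovers_half_splits(self):
        bound, _, _ = fixture_params("no_footprint", S=1, L=16)
        unbound = UnboundParams(alpha_o=[2.0], lambda0_bar_o=[20.0])
        naked = simulate_dataset(bound, unbound, N=4000, S=1, L=16, mix=0.0, seed=4)
        chrom_b, chrom_u, _ = fixture_params("footprint_strong", S=1, L=16)
        chrom = simulate_dataset(chrom_b, chrom_u, N=500, S=1, L=16, mix=0.4, seed=6)
        fit = fit_flexbg(build_pyramid_stack(naked.counts),
                         build_pyramid_stack(chrom.counts))
        for pj in fit.unbound.p_bar_o:
            np.testing.assert_allclose(pj, 0.5, atol=0.02)

    def test_spiked_background_split_recovered(self):
        J, L = 4, 16
        p_o = [np.full(2**j, 0.5) for j in range(J)]
        p_o[-1][4] = 0.8
        gen_bg = UnboundParams(alpha_o=[2.0], lambda0_bar_o=[15.0], flexbg=True,
                               p_bar_o=p_o, tau_o=np.full(J, 20.0))
        gen_b = BoundParams(p_bar=[np.full(2**j, 0.5) for j in range(J)],
                            tau=np.full(J, 1e6), alpha=[2.0], lambda0_bar=[15.0])
        naked = simulate_dataset(gen_b, gen_bg, N=3000, S=1, L=L, mix=0.0, seed=9)
        chrom_b, chrom_u, _ = fixture_params("footprint_strong", S=1, L=L)
        chrom = simulate_dataset(chrom_b, chrom_u, N=500, S=1, L=L, mix=0.4, seed=10)
        fit = fit_flexbg(build_pyramid_stack(naked.counts),
                         build_pyramid_stack(chrom.counts))
        assert abs(fit.unbound.p_bar_o[-1][4] - 0.8) < 0.03

    def test_stage_two_never_touches_background_profile(self):
        bound, unbound, _ = fixture_params("footprint_strong", S=1, L=16)
        naked = simulate_dataset(
            *fixture_params("no_footprint", S=1, L=16)[:2],
            N=800, S=1, L=16, mix=0.0, seed=1)
        chrom = simulate_dataset(bound, unbound, N=300, S=1, L=16, mix=0.4, seed=2)
        naked_stack = build_pyramid_stack(naked.counts)
        from msfoot.inference import _fit_beta_block

        fit = fit_flexbg(naked_stack, build_pyramid_stack(chrom.counts))
        # refit stage 1 alone and compare bitwise
        refit = fit_flexbg(naked_stack, build_pyramid_stack(chrom.counts),
                           config=EMConfig(max_iter=1))
        for a, b in zip(fit.unbound.p_bar_o, refit.unbound.p_bar_o):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(fit.unbound.tau_o, refit.unbound.tau_o)

    def test_missing_naked_dna_is_a_configuration_error(self, footprint_strong_stack):
        with pytest.raises(ValueError, match="naked-DNA"):
            fit_flexbg(None, footprint_strong_stack)


class TestPosteriorOdds:
    def test_log_odds_match_probability_identity(self, footprint_strong_stack):
        fit = fit_mixture(footprint_strong_stack)
        res = posterior_odds(footprint_strong_stack, fit)
        # identity is exact where the probability is not float-saturated
        ok = (res.posterior_prob > 1e-6) & (res.posterior_prob < 1 - 1e-6)
        assert ok.sum() > 10
        np.testing.assert_allclose(
            res.log_posterior_odds[ok],
            np.log(res.posterior_prob[ok]) - np.log1p(-res.posterior_prob[ok]),
            rtol=1e-8,
        )

    def test_ranking_by_odds_equals_ranking_by_probability(self, footprint_strong_stack):
        fit = fit_mixture(footprint_strong_stack)
        res = posterior_odds(footprint_strong_stack, fit)
        np.testing.assert_array_equal(
            np.argsort(res.log_posterior_odds), np.argsort(res.posterior_prob)
        )
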