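"""EM model: E-step exactness, objective ascent, shrinkage behaviour."""

import numpy as np
import pytest

from templateica import priors, synthetic, template_em
from templateica.types import BoldRun, GroupMaps, PriorTemplate, ReducedData


def _conditioning_oracle(y, A, noise_var, mu0, sigma0_sq):
    """Posterior of s given y via brute-force joint-Gaussian conditioning."""
    S0 = np.diag(sigma0_sq)
    C_yy = A @ S0 @ A.T + noise_var * np.eye(A.shape[0])
    C_sy = S0 @ A.T
    K = C_sy @ np.linalg.inv(C_yy)
    mean = mu0 + K @ (y - A @ mu0)
    cov = S0 - K @ C_sy.T
    return mean, cov


def _simulate_reduced(rng, Tr=8, Q=3, V=400, noise_var=0.5, mu_scale=1.0,
                      sigma0=None):
    mu0 = mu_scale * rng.normal(size=(Q, V))
    if sigma0 is None:
        sigma0 = rng.uniform(0.2, 1.0, size=(Q, V))
    A = rng.normal(size=(Tr, Q))
    s = mu0 + rng.normal(size=(Q, V)) * np.sqrt(sigma0)
    y = A @ s + rng.normal(size=(Tr, V)) * np.sqrt(noise_var)
    reduced = ReducedData(y=y, projection=np.eye(Tr), resid_var0=noise_var)
    template = PriorTemplate(
        mu0=mu0, sigma0_sq=sigma0, sigma_tot_sq=sigma0,
        sigma_noise_sq=np.zeros_like(sigma0), n_subjects_used=0,
    )
    return reduced, template, A, s


class TestReduceDimension:
    def test_exact_low_rank(self, rng):
        T, V, Q = 30, 50, 4
        A = rng.normal(size=(T, Q))
        S = rng.normal(size=(Q, V))
        run = BoldRun((A - A.mean(0)) @ S, 0.392)
        red = template_em.reduce_dimension(run, Q)
        assert red.resid_var0 == pytest.approx(0.0, abs=1e-12)
        recon = red.projection.T @ red.y
        np.testing.assert_allclose(recon, run.data - run.data.mean(0), atol=1e-8)

    def test_white_noise_residual_variance(self, rng):
        T, V, k = 100, 4000, 10
        sd = 1.7
        run = BoldRun(rng.normal(scale=sd, size=(T, V)), 0.392)
        red = template_em.reduce_dimension(run, k)
        expected = sd**2 * (1 - k / T)
        assert red.resid_var0 == pytest.approx(expected, rel=0.10)

    def test_projection_orthonormal_idempotent(self, rng):
        run = BoldRun(rng.normal(size=(40, 60)), 0.392)
        red = template_em.reduce_dimension(run, 6)
        np.testing.assert_allclose(red.projection @ red.projection.T,
                                   np.eye(6), atol=1e-10)
        # applying the projector twice fixes the retained subspace
        proj = red.projection.T @ red.projection
        np.testing.assert_allclose(proj @ proj, proj, atol=1e-10)

    def test_rejects_too_many_components(self, rng):
        run = BoldRun(rng.normal(size=(20, 30)), 0.392)
        with pytest.raises(ValueError):
            template_em.reduce_dimension(run, 20)


class TestPosteriorGivenParams:
    def test_full_shrinkage_zero_prior_variance(self, rng):
        Tr, Q = 6, 3
        A = rng.normal(size=(Tr, Q))
        mu0 = rng.normal(size=Q)
        mean, cov = template_em.posterior_given_params(
            rng.normal(size=Tr), A, 1.0, mu0, np.zeros(Q)
        )
        np.testing.assert_array_equal(mean, mu0)
        np.testing.assert_array_equal(cov, np.zeros((Q, Q)))

    def test_uninformative_likelihood_limit(self, rng):
        Tr, Q = 6, 3
        A = rng.normal(size=(Tr, Q))
        mu0 = rng.normal(size=Q)
        s0 = rng.uniform(0.5, 2.0, size=Q)
        mean, cov = template_em.posterior_given_params(
            rng.normal(size=Tr), A, 1e12, mu0, s0
        )
        np.testing.assert_allclose(mean, mu0, atol=1e-6)
        np.testing.assert_allclose(cov, np.diag(s0), atol=1e-6)

    def test_matches_joint_conditioning_oracle(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(120):
            Tr = int(rng.integers(3, 9))
            Q = int(rng.integers(2, 5))
            A = rng.normal(size=(Tr, Q))
            mu0 = rng.normal(size=Q)
            s0 = rng.uniform(0.1, 2.0, size=Q)
            nv = float(rng.uniform(0.2, 3.0))
            y = rng.normal(size=Tr)
            mean, cov = template_em.posterior_given_params(y, A, nv, mu0, s0)
            mean_o, cov_o = _conditioning_oracle(y, A, nv, mu0, s0)
            worst = max(worst,
                        np.abs(mean - mean_o).max(), np.abs(cov - cov_o).max())
        assert worst < 1e-8

    def test_partial_hard_constraint(self, rng):
        Tr, Q = 7, 4
        A = rng.normal(size=(Tr, Q))
        mu0 = rng.normal(size=Q)
        s0 = np.array([0.8, 0.0, 1.2, 0.0])
        y = rng.normal(size=Tr)
        mean, cov = template_em.posterior_given_params(y, A, 0.7, mu0, s0)
        assert mean[1] == mu0[1] and mean[3] == mu0[3]
        assert np.all(cov[[1, 3], :] == 0) and np.all(cov[:, [1, 3]] == 0)
        # free components match the oracle on the constrained residual
        free = s0 > 0
        mean_o, cov_o = _conditioning_oracle(
            y - A[:, ~free] @ mu0[~free], A[:, free], 0.7, mu0[free], s0[free]
        )
        np.testing.assert_allclose(mean[free], mean_o, atol=1e-10)
        np.testing.assert_allclose(cov[np.ix_(free, free)], cov_o, atol=1e-10)

    def test_rejects_negative_prior_variance(self, rng):
        with pytest.raises(ValueError):
            template_em.posterior_given_params(
                np.zeros(3), rng.normal(size=(3, 2)), 1.0,
                np.zeros(2), np.array([0.5, -0.1]),
            )


class TestEmFit:
    def test_fixed_point_near_generative_parameters(self, rng):
        reduced, template, A_true, _ = _simulate_reduced(rng, V=2000)
        post = template_em.em_fit(reduced, template, A_true, tol=1e-12,
                                  max_iter=1)
        assert np.linalg.norm(post.mixing - A_true) / np.linalg.norm(A_true) < 0.05
        assert post.noise_var == pytest.approx(0.5, rel=0.15)
        # posterior equals the vertex-wise closed form at the fitted params
        v = 7
        mean, cov = template_em.posterior_given_params(
            reduced.y[:, v], post.mixing, post.noise_var,
            template.mu0[:, v], template.sigma0_sq[:, v],
        )
        np.testing.assert_allclose(post.post_mean[:, v], mean, atol=1e-10)
        np.testing.assert_allclose(post.post_sd[:, v],
                                   np.sqrt(np.diag(cov)), atol=1e-10)

    def test_zero_prior_variance_returns_prior_mean(self, rng):
        reduced, template, A_true, _ = _simulate_reduced(rng, V=100)
        template.sigma0_sq[:] = 0.0
        post = template_em.em_fit(reduced, template, A_true, max_iter=20)
        np.testing.assert_array_equal(post.post_mean, template.mu0)
        np.testing.assert_array_equal(post.post_sd, 0.0)

    def test_objective_monotone(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            reduced, template, A_true, _ = _simulate_reduced(rng, V=300)
            init = A_true + rng.normal(scale=0.5, size=A_true.shape)
            post = template_em.em_fit(reduced, template, init, tol=1e-8,
                                      max_iter=40)
            diffs = np.diff(post.loglik_trace)
            assert np.all(diffs > -1e-8 * np.abs(post.loglik_trace[:-1]))

    def test_posterior_sd_bounded_by_prior_sd(self, rng):
        reduced, template, A_true, _ = _simulate_reduced(rng, V=200)
        post = template_em.em_fit(reduced, template, A_true, max_iter=30)
        assert np.all(post.post_sd <= np.sqrt(template.sigma0_sq) + 1e-12)

    def test_noise_pulls_posterior_toward_prior_mean(self, rng):
        dists = []
        for noise in (0.1, 100.0):
            r2 = np.random.default_rng(0)
            reduced, template, A_true, _ = _simulate_reduced(
                r2, V=300, noise_var=noise
            )
            post = template_em.em_fit(reduced, template, A_true, max_iter=30)
            dists.append(np.abs(post.post_mean - template.mu0).mean())
        assert dists[1] < dists[0]

    def test_longer_data_improves_recovery(self):
        # more frames in the run -> posterior mean closer to the true maps
        mesh = synthetic.make_mesh(200, "sphere", seed=2)
        errs = []
        for T in (60, 600):
            truth = synthetic.sample_truth(mesh, 2, 3, T, noise_sd=3.0, seed=4)
            template = PriorTemplate(
                mu0=truth.group_maps, sigma0_sq=truth.between_var,
                sigma_tot_sq=truth.between_var,
                sigma_noise_sq=np.zeros_like(truth.between_var),
                n_subjects_used=0,
            )
            run = synthetic.render_bold(truth, 0)
            post = template_em.fit_subject(run, template)
            errs.append(np.abs(post.post_mean - truth.subject_maps[0]).mean())
        assert errs[1] < errs[0]

    def test_nonconvergence_flagged_not_raised(self, rng):
        reduced, template, A_true, _ = _simulate_reduced(rng, V=100)
        init = A_true + rng.normal(scale=1.0, size=A_true.shape)
        post = template_em.em_fit(reduced, template, init, tol=1e-300,
                                  max_iter=3)
        assert post.converged is False
        assert post.n_iterations == 3

    def test_rank_deficient_init_rejected(self, rng):
        reduced, template, A_true, _ = _simulate_reduced(rng, V=50)
        bad = A_true.copy()
        bad[:, 1] = bad[:, 0]
        with pytest.raises(ValueError, match="full column rank"):
            template_em.em_fit(reduced, template, bad)


class TestExpectedCompleteLoglik:
    def _naive(self, reduced, template, post_mean, post_cov, A, noise_var):
        # brute-force elementwise summation over vertices and components
        y = reduced.y
        Tr, V = y.shape
        Q = post_mean.shape[0]
        total = 0.0
        for v in range(V):
            m, C = post_mean[:, v], post_cov[v]
            Eres = (y[:, v] @ y[:, v] - 2 * y[:, v] @ A @ m
                    + np.trace(A.T @ A @ (C + np.outer(m, m))))
            total += -0.5 * Tr * np.log(2 * np.pi * noise_var) - Eres / (2 * noise_var)
            for q in range(Q):
                s0 = template.sigma0_sq[q, v]
                if s0 > 0:
                    dev = C[q, q] + (m[q] - template.mu0[q, v]) ** 2
                    total += -0.5 * np.log(2 * np.pi * s0) - dev / (2 * s0)
        return total

    def test_matches_bruteforce_on_toy(self, rng):
        reduced, template, A, _ = _simulate_reduced(rng, Tr=5, Q=3, V=3)
        post = template_em.em_fit(reduced, template, A, max_iter=2)
        m, C = template_em._e_step(reduced.y, post.mixing, post.noise_var,
                                   template.mu0, template.sigma0_sq)
        got = template_em.expected_complete_loglik(
            reduced, template, m, C, post.mixing, post.noise_var
        )
        want = self._naive(reduced, template, m, C, post.mixing, post.noise_var)
        assert got == pytest.approx(want, rel=1e-10)

    def test_generative_parameters_beat_perturbed_ones(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            reduced, template, A_true, _ = _simulate_reduced(rng, V=400)
            def value(A, nv):
                m, C = template_em._e_step(reduced.y, A, nv, template.mu0,
                                           template.sigma0_sq)
                return template_em.expected_complete_loglik(
                    reduced, template, m, C, A, nv)
            perturbed = A_true + rng.normal(scale=1.0, size=A_true.shape)
            wins += value(A_true, 0.5) > value(perturbed, 0.5)
        assert wins >= 8


def test_fit_subject_uses_dual_regression_scale(small_truth, group_maps):
    # posterior maps come back on the scale of the template maps
    template = PriorTemplate(
        mu0=small_truth.group_maps, sigma0_sq=small_truth.between_var,
        sigma_tot_sq=small_truth.between_var,
        sigma_noise_sq=np.zeros_like(small_truth.between_var),
        n_subjects_used=0,
    )
    run = synthetic.render_bold(small_truth, 3)
    post = template_em.fit_subject(run, template)
    slope = np.polyfit(small_truth.subject_maps[3].ravel(),
                       post.post_mean.ravel(), 1)[0]
    assert 0.7 < slope < 1.3
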