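"""Parametric empirical Bayes, Bayesian model reduction and averaging."""

import numpy as np
import pytest
from scipy import integrate, stats

from epiforage.invert import GaussianPosterior
from epiforage.peb import (
    EFFECT_NAMES,
    N_EFFECTS,
    OFF_VARIANCE,
    bma,
    bmr,
    default_eta_prior,
    peb_design,
    peb_fit,
    search_model_space,
    _reduced_prior_for_pattern,
)


def gauss(mu, Sigma, log_evidence=0.0):
    return GaussianPosterior(
        mu=np.atleast_1d(np.asarray(mu, dtype=float)),
        Sigma=np.atleast_2d(np.asarray(Sigma, dtype=float)),
        log_evidence=log_evidence,
    )


def quadrature_delta_f(mu, s2, mu0, s02, mur0, sr02, lo=-30, hi=30):
    """1-d evidence-ratio oracle by numerical integration.

    The likelihood implied by a Gaussian prior/posterior pair is recovered
    pointwise as posterior x evidence / prior; integrating it against the
    reduced prior gives the reduced evidence.
    """
    prior = stats.norm(mu0, np.sqrt(s02))
    post = stats.norm(mu, np.sqrt(s2))
    red = stats.norm(mur0, np.sqrt(sr02))

    def integrand(x):
        return np.exp(post.logpdf(x) - prior.logpdf(x) + red.logpdf(x))

    # break points let QUADPACK resolve near-delta reduced priors
    pts = sorted({mu, mu0, mur0})
    val, _ = integrate.quad(integrand, lo, hi, limit=500, points=pts)
    return np.log(val)


class TestDesign:
    def test_constant_and_exponential_decay_columns(self):
        X = peb_design(5)
        np.testing.assert_array_equal(X[:, 0], 1.0)
        np.testing.assert_allclose(X[:, 1], np.exp(-(np.arange(1, 6) - 1.0)))


class TestBMR:
    def test_identity_reduction_is_exact_zero(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3))
        Sigma = A @ A.T + np.eye(3)
        prior = gauss(np.zeros(3), np.eye(3))
        post = gauss(rng.normal(size=3), 0.5 * Sigma)
        dF, red = bmr(post, prior, gauss(np.zeros(3), np.eye(3)))
        assert dF == 0.0
        np.testing.assert_array_equal(red.mu, post.mu)

    @pytest.mark.parametrize(
        "mu,s2,mu0,s02,mur0,sr02",
        [
            (0.8, 0.2, 0.0, 1.0, 0.0, 0.05),
            (-0.3, 0.5, 0.1, 2.0, 0.5, 1.0),
            (1.5, 0.1, 0.0, 0.5, 0.0, 1e-4),
        ],
    )
    def test_one_dimensional_matches_quadrature(self, mu, s2, mu0, s02, mur0, sr02):
        dF, _ = bmr(gauss(mu, s2), gauss(mu0, s02), gauss(mur0, sr02))
        want = quadrature_delta_f(mu, s2, mu0, s02, mur0, sr02)
        assert dF == pytest.approx(want, abs=1e-6)

    def test_two_dimensional_matches_quadrature(self):
        prior = gauss([0.0, 0.0], np.eye(2))
        post = gauss([0.7, -0.4], [[0.3, 0.1], [0.1, 0.4]])
        red = gauss([0.0, 0.0], np.diag([1.0, 1e-3]))
        dF, _ = bmr(post, prior, red)

        # 2-d quadrature over the implied likelihood times the reduced prior
        Pp = np.linalg.inv(prior.Sigma)
        P = np.linalg.inv(post.Sigma)
        Pr = np.linalg.inv(red.Sigma)

        def logpdf(x, mu, Prec):
            d = x - mu
            sign, logdet = np.linalg.slogdet(Prec / (2 * np.pi))
            return 0.5 * logdet - 0.5 * d @ Prec @ d

        def integrand(y, x):
            v = np.array([x, y])
            return np.exp(
                logpdf(v, post.mu, P) - logpdf(v, prior.mu, Pp) + logpdf(v, red.mu, Pr)
            )

        val, _ = integrate.dblquad(integrand, -8, 8, -8, 8, epsabs=1e-10)
        assert dF == pytest.approx(np.log(val), abs=1e-6)

    def test_switching_off_a_strong_effect_is_penalised(self):
        # posterior mean far from zero: shrinking that prior toward a point
        # mass at zero must lose evidence
        prior = gauss([0.0], [[1.0]])
        post = gauss([1.2], [[0.1]])
        dF, _ = bmr(post, prior, gauss([0.0], [[1e-4]]))
        assert dF < 0
        want = quadrature_delta_f(1.2, 0.1, 0.0, 1.0, 0.0, 1e-4)
        assert dF == pytest.approx(want, rel=1e-5)
        # the harder the shrinkage, the larger the penalty
        dF_off, _ = bmr(post, prior, gauss([0.0], [[OFF_VARIANCE]]))
        assert dF_off < dF

    def test_reduction_is_additive_along_a_chain(self):
        rng = np.random.default_rng(4)
        prior = gauss(np.zeros(2), np.eye(2))
        post = gauss(rng.normal(size=2), [[0.4, 0.05], [0.05, 0.3]])
        mid = gauss([0.1, -0.1], 0.5 * np.eye(2))
        final = gauss([0.0, 0.0], np.diag([0.2, 0.1]))
        dF1, post_mid = bmr(post, prior, mid)
        dF2, _ = bmr(post_mid, mid, final)
        dF_direct, _ = bmr(post, prior, final)
        assert dF1 + dF2 == pytest.approx(dF_direct, abs=1e-9)

    def test_indefinite_reduction_flagged_invalid(self):
        prior = gauss([0.0], [[0.1]])
        post = gauss([0.0], [[0.2]])  # posterior wider than prior (improper)
        wide = gauss([0.0], [[50.0]])
        dF, red = bmr(post, prior, wide)
        assert dF == -np.inf and red is None


class TestPEBFit:
    def _blocks(self, eta, noise_sd, rng, between=0.0):
        X = peb_design(5)
        posts = []
        for b in range(5):
            mean = np.array(
                [
                    X[b] @ np.array([eta[p], eta[4 + p]])
                    for p in range(4)
                ]
            )
            obs = mean + rng.normal(0, noise_sd, size=4) + rng.normal(0, between, 4)
            posts.append(gauss(obs, noise_sd**2 * np.eye(4)))
        return posts

    def test_constant_blocks_give_null_decay(self):
        rng = np.random.default_rng(10)
        eta = np.array([0.5, -0.3, 0.2, 0.0, 0, 0, 0, 0], dtype=float)
        posts = self._blocks(eta, 0.05, rng)
        peb = peb_fit(posts)
        decay = peb.eta_posterior.mu[4:]
        sd = np.sqrt(np.diag(peb.eta_posterior.Sigma))[4:]
        assert np.all(np.abs(decay) < 2.5 * sd)

    def test_matches_direct_gls_oracle(self):
        rng = np.random.default_rng(11)
        posts = self._blocks(rng.normal(size=8), 0.1, rng)
        prior = default_eta_prior()
        peb = peb_fit(posts, eta_prior=prior)

        # independent generalized-least-squares computation
        X = np.kron(peb_design(5), np.eye(4))
        m = np.concatenate([p.mu for p in posts])
        V = np.zeros((20, 20))
        for b, p in enumerate(posts):
            V[4 * b : 4 * b + 4, 4 * b : 4 * b + 4] = p.Sigma + np.eye(4) / 16.0
        W = np.linalg.inv(V)
        P = np.linalg.inv(prior.Sigma) + X.T @ W @ X
        mu = np.linalg.solve(P, X.T @ W @ m)
        np.testing.assert_allclose(peb.eta_posterior.mu, mu, atol=1e-10)
        np.testing.assert_allclose(peb.eta_posterior.Sigma, np.linalg.inv(P), atol=1e-10)

    def test_known_decay_recovered_across_replications(self):
        rng = np.random.default_rng(12)
        eta = np.zeros(8)
        eta[6] = -0.5  # decay on the third within-block parameter
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            posts = self._blocks(eta, 0.08, rng)
            peb = peb_fit(posts)
            mu = peb.eta_posterior.mu[6]
            sd = np.sqrt(peb.eta_posterior.Sigma[6, 6])
            if mu - 1.645 * sd <= eta[6] <= mu + 1.645 * sd:
                hits += 1
        assert hits >= 0.85 * n_rep

    def test_missing_block_rejected(self):
        rng = np.random.default_rng(13)
        posts = self._blocks(np.zeros(8), 0.1, rng)[:4]
        with pytest.raises(ValueError):
            peb_fit(posts)


class TestModelSpace:
    def _null_peb(self, seed=14):
        rng = np.random.default_rng(seed)
        posts = TestPEBFit()._blocks(np.zeros(8), 0.08, rng)
        return peb_fit(posts)

    def test_space_has_256_models_over_8_effects(self):
        space = search_model_space(self._null_peb())
        assert space.n_models == 256
        assert space.patterns.shape == (256, N_EFFECTS)
        assert len(EFFECT_NAMES) == 8
        assert space.posterior_prob.sum() == pytest.approx(1.0)

    def test_null_cohort_prefers_sparse_models(self):
        space = search_model_space([self._null_peb(s) for s in (20, 21, 22)])
        # the all-off pattern should be among the best few models
        rank = np.argsort(-space.pooled_logev)
        null_index = int(np.where(~space.patterns.any(axis=1))[0][0])
        assert null_index in rank[:8]

    def test_softmax_invariant_to_constant_shift(self):
        space = search_model_space(self._null_peb())
        z = space.pooled_logev + 123.4
        p = np.exp(z - z.max())
        p /= p.sum()
        np.testing.assert_allclose(p, space.posterior_prob, atol=1e-12)


class TestBMA:
    def test_single_certain_model_passes_through(self):
        peb = TestModelSpace()._null_peb()
        space = search_model_space(peb)
        # force certainty on the full model (all effects on)
        space.posterior_prob[:] = 0.0
        full_idx = int(np.where(space.patterns.all(axis=1))[0][0])
        space.posterior_prob[full_idx] = 1.0
        avg = bma(space, space.reduced_posteriors[0])
        ref = space.reduced_posteriors[0][full_idx]
        np.testing.assert_allclose(avg.mu, ref.mu, atol=1e-12)
        np.testing.assert_allclose(avg.Sigma, ref.Sigma, atol=1e-12)

    def test_symmetric_mixture_moments(self):
        peb = TestModelSpace()._null_peb()
        space = search_model_space(peb)
        a, s2 = 0.7, 0.04
        posts = [
            gauss(np.full(8, +a), s2 * np.eye(8)),
            gauss(np.full(8, -a), s2 * np.eye(8)),
        ] + [None] * (space.n_models - 2)
        space.posterior_prob[:] = 0.0
        space.posterior_prob[:2] = 0.5
        avg = bma(space, posts)
        np.testing.assert_allclose(avg.mu, 0.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(avg.Sigma), a**2 + s2, atol=1e-12)

    def test_total_variance_never_below_component(self):
        peb = TestModelSpace()._null_peb()
        space = search_model_space(peb)
        avg = bma(space, space.reduced_posteriors[0])
        # along any direction where component means disagree, mixture
        # variance must dominate the smallest component variance
        probs = space.posterior_prob
        top = np.argsort(-probs)[:5]
        for i in top:
            post = space.reduced_posteriors[0][i]
            if post is None:
                continue
            direction = np.ones(8) / np.sqrt(8)
            v_mix = direction @ avg.Sigma @ direction
            v_comp = direction @ post.Sigma @ direction
            gap = (direction @ (post.mu - avg.mu)) ** 2
            # law of total variance lower bound via this component alone
            assert v_mix + 1e-12 >= probs[i] * (v_comp + gap)


def test_reduced_prior_pattern_construction():
    prior = default_eta_prior()
    pattern = np.array([True] * 4 + [False] * 4)
    red = _reduced_prior_for_pattern(prior, pattern)
    np.testing.assert_allclose(np.diag(red.Sigma)[:4], 0.25)
    np.testing.assert_allclose(np.diag(red.Sigma)[4:], OFF_VARIANCE)
    assert np.all(red.mu == 0.0)
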