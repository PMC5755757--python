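"""Parametric empirical Bayes over blocks, Bayesian model reduction and averaging.

Block-wise changes in the four subject parameters are modelled with a
between-block general linear model comprising a constant and an exponential
decay with a time constant of one block: regressors ``1`` and
``exp(-(b - 1))`` for block ``b = 1..5``. The 8 second-level effects
(4 parameters x 2 regressors) span a space of 2^8 = 256 reduced models,
compared analytically by Bayesian model reduction; evidence is pooled
(summed) over subjects and a softmax yields posterior model probabilities,
from which Bayesian model averages are formed by moment matching.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .invert import PARAM_NAMES, GaussianPosterior

N_WITHIN = 4  # within-block parameters
N_REGRESSORS = 2  # constant + exponential decay
N_EFFECTS = N_WITHIN * N_REGRESSORS

#: second-level effect names: four constants then four decay terms
EFFECT_NAMES = tuple(
    [f"{p}_const" for p in PARAM_NAMES] + [f"{p}_decay" for p in PARAM_NAMES]
)

#: prior variance encoding a switched-off effect (numerical point mass at 0)
OFF_VARIANCE = 1e-8

#: fixed between-block (random effects) covariance scale
DEFAULT_BETWEEN_VAR = 1.0 / 16.0


def peb_design(n_blocks: int = 5) -> np.ndarray:
    """Design matrix: a constant column and exp(-(b - 1)) for b = 1..n."""
    b = np.arange(1, n_blocks + 1)
    return np.column_stack([np.ones(n_blocks), np.exp(-(b - 1.0))])


@dataclass
class PEBModel:
    """Second-level Gaussian linear model over one subject's block posteriors."""

    X: np.ndarray
    eta_prior: GaussianPosterior
    eta_posterior: GaussianPosterior


def default_eta_prior() -> GaussianPosterior:
    """Zero-mean prior on the 8 effects, variance 0.25 per coordinate."""
    return GaussianPosterior(
        mu=np.zeros(N_EFFECTS), Sigma=0.25 * np.eye(N_EFFECTS), log_evidence=0.0
    )


def peb_fit(
    block_posteriors: list[GaussianPosterior],
    X: np.ndarray | None = None,
    eta_prior: GaussianPosterior | None = None,
    between_var: float = DEFAULT_BETWEEN_VAR,
) -> PEBModel:
    """Closed-form PEB: block posterior means regressed on the design.

    Block means are treated as noisy observations of ``X eta`` with noise
    covariance equal to each block's posterior covariance plus a fixed
    between-block covariance ``between_var * I``. Effects are ordered as
    the four constants followed by the four decay coefficients
    (:data:`EFFECT_NAMES`).
    """
    if X is None:
        X = peb_design()  # the balanced 5-block design
    if len(block_posteriors) != X.shape[0]:
        raise ValueError(
            f"need {X.shape[0]} block posteriors, got {len(block_posteriors)}"
        )
    if eta_prior is None:
        eta_prior = default_eta_prior()
    d = N_WITHIN
    # observation vector and noise covariance (block-diagonal)
    m = np.concatenate([bp.mu for bp in block_posteriors])
    n_obs = len(m)
    V = np.zeros((n_obs, n_obs))
    for b, bp in enumerate(block_posteriors):
        V[b * d : (b + 1) * d, b * d : (b + 1) * d] = bp.Sigma + between_var * np.eye(d)
    # design on the stacked observations: effect order (constants, decays)
    # maps regressor r, parameter p to column r * d + p
    Xk = np.kron(X, np.eye(d))
    Vi = np.linalg.inv(V)
    P0 = np.linalg.inv(eta_prior.Sigma)
    P = P0 + Xk.T @ Vi @ Xk
    Sigma = np.linalg.inv(P)
    Sigma = 0.5 * (Sigma + Sigma.T)
    mu = Sigma @ (Xk.T @ Vi @ m + P0 @ eta_prior.mu)
    # marginal likelihood of the block means under the hierarchical Gaussian
    marg_cov = Xk @ eta_prior.Sigma @ Xk.T + V
    log_ev = float(
        stats.multivariate_normal.logpdf(m, mean=Xk @ eta_prior.mu, cov=marg_cov)
    )
    post = GaussianPosterior(
        mu=mu, Sigma=Sigma, log_evidence=log_ev, n_trials=len(block_posteriors)
    )
    return PEBModel(X=X, eta_prior=eta_prior, eta_posterior=post)


def bmr(
    posterior: GaussianPosterior,
    prior: GaussianPosterior,
    reduced_prior: GaussianPosterior,
) -> tuple[float, GaussianPosterior | None]:
    """Analytic evidence change and posterior under a reduced prior.

    Given a Gaussian prior/posterior pair from a fitted model, the evidence
    and posterior of a model differing only in its prior follow in closed
    form from the precision-weighted means. Returns ``(delta_F,
    reduced_posterior)``; a reduction rendering the posterior precision
    indefinite is flagged invalid with ``-inf`` evidence.
    """
    if np.array_equal(reduced_prior.mu, prior.mu) and np.array_equal(
        reduced_prior.Sigma, prior.Sigma
    ):
        return 0.0, posterior
    P = np.linalg.inv(posterior.Sigma)
    P0 = np.linalg.inv(prior.Sigma)
    Pr0 = np.linalg.inv(reduced_prior.Sigma)
    Pr = P + Pr0 - P0
    sign, _ = np.linalg.slogdet(Pr)
    if sign <= 0:
        return -np.inf, None
    try:
        np.linalg.cholesky(Pr)
    except np.linalg.LinAlgError:
        return -np.inf, None
    Sr = np.linalg.inv(Pr)
    Sr = 0.5 * (Sr + Sr.T)
    mu_r = Sr @ (P @ posterior.mu + Pr0 @ reduced_prior.mu - P0 @ prior.mu)
    logdet = lambda M: np.linalg.slogdet(M)[1]
    dF = 0.5 * (logdet(P) - logdet(Pr) + logdet(Pr0) - logdet(P0)) + 0.5 * (
        mu_r @ Pr @ mu_r
        - posterior.mu @ P @ posterior.mu
        - reduced_prior.mu @ Pr0 @ reduced_prior.mu
        + prior.mu @ P0 @ prior.mu
    )
    reduced = GaussianPosterior(
        mu=mu_r, Sigma=Sr, log_evidence=posterior.log_evidence + float(dF)
    )
    return float(dF), reduced


def _reduced_prior_for_pattern(
    prior: GaussianPosterior, pattern: np.ndarray
) -> GaussianPosterior:
    """Prior with switched-off effects shrunk to a numerical point mass at 0."""
    Sigma = prior.Sigma.copy()
    mu = prior.mu.copy()
    off = ~pattern
    # zero covariances with the switched-off coordinates, shrink their variance
    Sigma[off, :] = 0.0
    Sigma[:, off] = 0.0
    Sigma[np.diag_indices_from(Sigma)] = np.where(
        pattern, np.diag(prior.Sigma), OFF_VARIANCE
    )
    mu[off] = 0.0
    return GaussianPosterior(mu=mu, Sigma=Sigma, log_evidence=0.0)


@dataclass
class ModelSpace:
    """All on/off patterns over the second-level effects, with pooled evidence."""

    patterns: np.ndarray  # (n_models, n_effects) bool
    pooled_logev: np.ndarray  # (n_models,)
    posterior_prob: np.ndarray  # softmax of pooled_logev
    per_subject_dF: np.ndarray  # (n_subjects, n_models)
    reduced_posteriors: list[list[GaussianPosterior | None]]  # [subject][model]

    @property
    def n_models(self) -> int:
        return len(self.patterns)

    @property
    def best_pattern(self) -> np.ndarray:
        return self.patterns[int(np.argmax(self.pooled_logev))]


def search_model_space(peb_models: list[PEBModel] | PEBModel) -> ModelSpace:
    """Score all 2^8 = 256 on/off combinations of the between-block effects.

    Each pattern's reduced prior switches the excluded effects off
    (prior variance :data:`OFF_VARIANCE`, mean 0); evidence changes are
    computed per subject by Bayesian model reduction, pooled by summation,
    and converted to posterior model probabilities with a softmax.
    """
    if isinstance(peb_models, PEBModel):
        peb_models = [peb_models]
    n_eff = len(peb_models[0].eta_posterior.mu)
    patterns = np.array(
        list(itertools.product([False, True], repeat=n_eff)), dtype=bool
    )
    n_models = len(patterns)
    dF = np.zeros((len(peb_models), n_models))
    reduced: list[list[GaussianPosterior | None]] = []
    for si, peb in enumerate(peb_models):
        row: list[GaussianPosterior | None] = []
        for mi, pattern in enumerate(patterns):
            rp = _reduced_prior_for_pattern(peb.eta_prior, pattern)
            f, post = bmr(peb.eta_posterior, peb.eta_prior, rp)
            dF[si, mi] = f
            row.append(post)
        reduced.append(row)
    pooled = dF.sum(axis=0)
    z = pooled - pooled.max()
    prob = np.exp(z)
    prob /= prob.sum()
    return ModelSpace(
        patterns=patterns,
        pooled_logev=pooled,
        posterior_prob=prob,
        per_subject_dF=dF,
        reduced_posteriors=reduced,
    )


def bma(
    model_space: ModelSpace, reduced_posteriors: list[GaussianPosterior | None]
) -> GaussianPosterior:
    """Moment-matched Bayesian model average of one subject's posteriors.

    Mixture weights are the model-space posterior probabilities; invalid
    reductions carry zero weight.
    """
    w = model_space.posterior_prob.copy()
    valid = np.array([p is not None for p in reduced_posteriors])
    w = np.where(valid, w, 0.0)
    w /= w.sum()
    d = len(model_space.patterns[0])
    mu = np.zeros(d)
    second = np.zeros((d, d))
    for wi, post in zip(w, reduced_posteriors):
        if wi == 0.0 or post is None:
            continue
        mu += wi * post.mu
        second += wi * (post.Sigma + np.outer(post.mu, post.mu))
    Sigma = second - np.outer(mu, mu)
    return GaussianPosterior(mu=mu, Sigma=0.5 * (Sigma + Sigma.T), log_evidence=0.0)
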