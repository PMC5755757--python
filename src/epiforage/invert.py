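"""Fitting subject-level prior-belief parameters to observed scan paths.

Four free parameters are estimated per subject (all in log/linear space as
named): ``ln_beta``, the log inverse precision of policy selection; ``E_h``,
the log bias toward the fixed-form heuristic policy; and ``ln_C_cor`` /
``ln_C_q``, log scaling coefficients on the preference tables for being
correct and for being quick.

The data are locations, not policy labels, so the likelihood of an observed
saccade marginalises the policy posterior onto its target location:
``P(L) = pi_L + pi_9 * [H(current) = L]``. Estimation is maximum a
posteriori under a Gaussian prior with a Laplace approximation to the log
evidence (posterior covariance from the finite-difference Hessian at the
optimum).

Belief posteriors, epistemic values and outcome predictives at each observed
step do not depend on the parameters, so they are precomputed once per
dataset (:class:`ScanPathStats`); preference terms are linear in the two
scale factors, which makes each likelihood evaluation a cheap vectorised
softmax. This is algebraically identical to replaying the inference loop at
every evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .generative_model import SceneModel, build_preferences, build_scene_model
from .inference import (
    InconsistentScanPathError,
    _epistemic_for_targets,
    action_targets,
    posterior_from_history,
)
from .labels import LOC_INDEX, WHAT_INDEX

#: per-step likelihood floor keeping the objective finite on outlier saccades
STEP_LIK_FLOOR = 1e-12


@dataclass
class SubjectParams:
    """The four free prior-belief parameters, in log space."""

    ln_beta: float = 0.0
    E_h: float = 0.0
    ln_C_cor: float = 0.0
    ln_C_q: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([self.ln_beta, self.E_h, self.ln_C_cor, self.ln_C_q])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "SubjectParams":
        return cls(*[float(x) for x in theta])


PARAM_NAMES = ("ln_beta", "E_h", "ln_C_cor", "ln_C_q")


@dataclass
class FitPriors:
    """Gaussian prior over the parameter vector."""

    mu0: np.ndarray
    Sigma0: np.ndarray


def default_fit_priors() -> FitPriors:
    """Weakly informative default: zero mean, variance 0.25 per coordinate."""
    return FitPriors(mu0=np.zeros(4), Sigma0=0.25 * np.eye(4))


@dataclass
class GaussianPosterior:
    """Laplace posterior over parameters with its approximate log evidence."""

    mu: np.ndarray
    Sigma: np.ndarray
    log_evidence: float
    n_trials: int = 0
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def credible_interval(self, level: float = 0.90) -> np.ndarray:
        """Central credible intervals per coordinate, shape (d, 2)."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        sd = np.sqrt(np.diag(self.Sigma))
        return np.stack([self.mu - z * sd, self.mu + z * sd], axis=1)


@dataclass
class ScanPathStats:
    """Parameter-free per-step sufficient statistics of a scan-path dataset."""

    epi: np.ndarray  # (S, 9) epistemic value per policy
    u_cor: np.ndarray  # (S, 9) expected what-utility at unit scale
    u_q: np.ndarray  # (S, 9) where-utility at unit scale
    obs_loc: np.ndarray  # (S,) observed next location index
    h_match: np.ndarray  # (S,) heuristic map targets the observed location
    n_trials: int = 0


def _trial_paths(trials: Sequence) -> list[list[tuple[int, str, str]]]:
    """Accept TrialRecord-like objects (``.path``) or raw path lists."""
    out = []
    for t in trials:
        out.append(t.path if hasattr(t, "path") else list(t))
    return out


def prepare_scanpaths(
    trials: Sequence, model: SceneModel | None = None, H: np.ndarray | None = None
) -> ScanPathStats:
    """Precompute per-step statistics for likelihood evaluation.

    Each trial's path must start at FIX. Raises
    :class:`InconsistentScanPathError` (naming the trial) if an observation
    sequence is impossible under every scene configuration.
    """
    if model is None:
        model = build_scene_model(H=H)
    if H is None:
        H = model.H
    base = build_preferences(0.0, 0.0, T=model.T)
    A = model.A_joint
    epi_rows, ucor_rows, uq_rows, obs_rows, hm_rows = [], [], [], [], []
    n_trials = 0
    for ti, path in enumerate(_trial_paths(trials)):
        if len(path) < 2:
            continue
        n_trials += 1
        history: list[tuple[int, int]] = []
        for i in range(len(path) - 1):
            step, loc, out = path[i]
            cur = LOC_INDEX[loc]
            if out in ("RIGHT", "WRONG"):
                break  # feedback ends the trial; nothing to predict from here
            try:
                history = history + [(cur, WHAT_INDEX[out])]
                q = posterior_from_history(model, history)
            except InconsistentScanPathError as err:
                raise InconsistentScanPathError(
                    f"trial index {ti}: {err}"
                ) from None
            tau = i + 1  # 1-based current step; outcome lands at tau + 1
            targets = action_targets(H, cur)
            epi_rows.append(_epistemic_for_targets(model, q, targets))
            p_o = np.einsum("ojt,j->ot", A[:, :, targets], q)
            ucor_rows.append(p_o.T @ base.C_what[:, tau])
            uq_rows.append(base.C_where[targets, tau])
            nxt = LOC_INDEX[path[i + 1][1]]
            obs_rows.append(nxt)
            hm_rows.append(H[cur] == nxt)
        # the final observation scores no action but must still be possible
        _, last_loc, last_out = path[-1]
        if last_out not in ("RIGHT", "WRONG"):
            try:
                posterior_from_history(
                    model, history + [(LOC_INDEX[last_loc], WHAT_INDEX[last_out])]
                )
            except InconsistentScanPathError as err:
                raise InconsistentScanPathError(f"trial index {ti}: {err}") from None
    if not epi_rows:
        raise ValueError("no scorable saccade steps in the supplied trials")
    return ScanPathStats(
        epi=np.asarray(epi_rows),
        u_cor=np.asarray(ucor_rows),
        u_q=np.asarray(uq_rows),
        obs_loc=np.asarray(obs_rows, dtype=int),
        h_match=np.asarray(hm_rows, dtype=bool),
        n_trials=n_trials,
    )


def loglik_from_stats(
    stats_: ScanPathStats, theta: np.ndarray, include_epistemic: bool = True
) -> float:
    """Action log likelihood (nats) of the observed saccades under theta."""
    ln_beta, E_h, ln_c_cor, ln_c_q = theta
    beta = np.exp(ln_beta)
    prag = np.exp(ln_c_cor) * stats_.u_cor + np.exp(ln_c_q) * stats_.u_q
    G = -prag
    if include_epistemic:
        G = G - stats_.epi
    logits = -G / beta
    logits[:, 8] += E_h
    logits -= logits.max(axis=1, keepdims=True)
    pi = np.exp(logits)
    pi /= pi.sum(axis=1, keepdims=True)
    S = len(stats_.obs_loc)
    p = pi[np.arange(S), stats_.obs_loc] + pi[:, 8] * stats_.h_match
    return float(np.log(np.maximum(p, STEP_LIK_FLOOR)).sum())


def action_loglik(
    trials: Sequence,
    params: SubjectParams,
    model: SceneModel | None = None,
    H: np.ndarray | None = None,
    include_epistemic: bool = True,
) -> float:
    """Log probability of every observed saccade under ``params``.

    Convenience wrapper building the sufficient statistics on the fly; use
    :func:`prepare_scanpaths` + :func:`loglik_from_stats` when evaluating
    many parameter vectors on the same data.
    """
    stats_ = prepare_scanpaths(trials, model=model, H=H)
    return loglik_from_stats(stats_, params.to_array(), include_epistemic)


def _log_prior(theta: np.ndarray, priors: FitPriors) -> float:
    return float(
        stats.multivariate_normal.logpdf(theta, mean=priors.mu0, cov=priors.Sigma0)
    )


def _neg_log_joint(
    theta: np.ndarray, stats_: ScanPathStats, priors: FitPriors, include_epistemic: bool
) -> float:
    return -(loglik_from_stats(stats_, theta, include_epistemic) + _log_prior(theta, priors))


def _fd_hessian(f, x: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian, symmetrised."""
    d = len(x)
    H = np.zeros((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * step**2)
    return 0.5 * (H + H.T)


def _spd_inverse(H: np.ndarray) -> tuple[np.ndarray, bool]:
    """Invert a Hessian, jittering the diagonal until positive definite."""
    jitter = 0.0
    for _ in range(12):
        try:
            L = np.linalg.cholesky(H + jitter * np.eye(len(H)))
            inv = np.linalg.inv(H + jitter * np.eye(len(H)))
            return 0.5 * (inv + inv.T), jitter == 0.0
        except np.linalg.LinAlgError:
            jitter = 1e-8 if jitter == 0.0 else jitter * 10.0
    raise np.linalg.LinAlgError("Hessian could not be regularised to SPD")


def fit_subject(
    trials: Sequence,
    priors: FitPriors | None = None,
    model: SceneModel | None = None,
    H: np.ndarray | None = None,
    include_epistemic: bool = True,
    stats_: ScanPathStats | None = None,
    start: np.ndarray | None = None,
) -> GaussianPosterior:
    """MAP estimate of the four parameters with a Laplace evidence approximation.

    Quasi-Newton ascent on the log joint from the prior mean; the posterior
    covariance is the inverse finite-difference Hessian of the negative log
    joint at the optimum, and ``log_evidence = loglik + log prior +
    (d/2) log 2 pi + (1/2) log det Sigma``.
    """
    if priors is None:
        priors = default_fit_priors()
    if stats_ is None:
        stats_ = prepare_scanpaths(trials, model=model, H=H)
    if stats_.n_trials < 10:
        import warnings

        warnings.warn(
            f"only {stats_.n_trials} trials; at least 10 are recommended",
            stacklevel=2,
        )
    obj = lambda th: _neg_log_joint(th, stats_, priors, include_epistemic)
    x0 = priors.mu0.copy() if start is None else np.asarray(start, dtype=float)
    res = optimize.minimize(obj, x0, method="L-BFGS-B")
    theta = res.x
    hess = _fd_hessian(obj, theta)
    Sigma, spd_ok = _spd_inverse(hess)
    d = len(theta)
    sign, logdet = np.linalg.slogdet(Sigma)
    loglik = loglik_from_stats(stats_, theta, include_epistemic)
    log_evidence = (
        loglik + _log_prior(theta, priors) + 0.5 * d * np.log(2 * np.pi) + 0.5 * logdet
    )
    return GaussianPosterior(
        mu=theta,
        Sigma=Sigma,
        log_evidence=float(log_evidence),
        n_trials=stats_.n_trials,
        converged=bool(res.success) and spd_ok and sign > 0,
        diagnostics={"loglik": loglik, "optimizer_message": str(res.message)},
    )


def evidence_epistemic_vs_extrinsic(
    trials: Sequence,
    priors: FitPriors | None = None,
    model: SceneModel | None = None,
    H: np.ndarray | None = None,
) -> tuple[float, GaussianPosterior, GaussianPosterior]:
    """Log-evidence difference between the full and extrinsic-only models.

    The reduced model zeroes the epistemic (uncertainty-resolving) term in
    expected free energy, leaving expected utility only; both models are
    fitted independently to the same scan paths. Positive values favour the
    epistemic account.
    """
    stats_ = prepare_scanpaths(trials, model=model, H=H)
    full = fit_subject(trials, priors, model=model, H=H, stats_=stats_)
    reduced = fit_subject(
        trials, priors, model=model, H=H, include_epistemic=False, stats_=stats_
    )
    return full.log_evidence - reduced.log_evidence, full, reduced
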