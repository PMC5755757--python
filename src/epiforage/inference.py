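"""Belief updating, expected free energy and policy selection.

Within a trial the context and flip factors are static and the sampling
location is observed, so the posterior over hidden states reduces to a
distribution over the 12 joint (context, vflip, hflip) configurations given
the fixation history. With a deterministic likelihood this posterior is
computed exactly by enumeration — the converged limit of the variational
scheme when the variational family covers the joint — and per-factor
marginals are read off from it.

Policies are evaluated one step ahead. The expected free energy of a policy
combines its epistemic value (expected Bayesian surprise: the expected KL
divergence between posterior and prior beliefs over the joint latents on
observing that saccade's outcome) and its pragmatic value (expected utility
under the log prior preferences). The posterior over the nine policies is a
softmax of E - F - G/beta, where E holds the fixed-form (heuristic) bias, F
is the past free energy (common to all policies here, hence zero), and beta
is the inverse precision of policy selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .generative_model import Preferences, PolicyPrior, SceneModel
from .labels import (
    FIX,
    LOCATIONS,
    LOC_INDEX,
    N_CONTEXTS,
    N_POLICIES,
    WHAT_INDEX,
)

#: log-floor applied to likelihood entries to keep log-domain quantities finite
LIKELIHOOD_FLOOR = float(np.exp(-16.0))


class InconsistentScanPathError(ValueError):
    """An observation has zero likelihood under every joint latent state."""


@dataclass
class Beliefs:
    """Posterior beliefs over hidden states given the within-trial history.

    ``q_joint`` is the posterior over the 12 joint (context, vflip, hflip)
    configurations; per-factor marginals are derived views. The location is
    observed, so ``Q_location`` is always a point mass on ``location``.
    """

    q_joint: np.ndarray
    location: int = FIX
    history: list[tuple[int, int]] = field(default_factory=list)

    @property
    def Q_context(self) -> np.ndarray:
        return self.q_joint.reshape(N_CONTEXTS, 2, 2).sum(axis=(1, 2))

    @property
    def Q_vflip(self) -> np.ndarray:
        return self.q_joint.reshape(N_CONTEXTS, 2, 2).sum(axis=(0, 2))

    @property
    def Q_hflip(self) -> np.ndarray:
        return self.q_joint.reshape(N_CONTEXTS, 2, 2).sum(axis=(0, 1))

    @property
    def Q_location(self) -> np.ndarray:
        q = np.zeros(len(LOCATIONS))
        q[self.location] = 1.0
        return q


def initial_beliefs(model: SceneModel) -> Beliefs:
    """Prior beliefs at the start of a trial (agent at central fixation)."""
    return Beliefs(q_joint=model.D_joint.copy(), location=FIX, history=[])


def posterior_from_history(
    model: SceneModel, history: list[tuple[int, int]]
) -> np.ndarray:
    """Exact joint posterior over the 12 latent states given (location, outcome) pairs."""
    A = model.A_joint  # (outcome, joint, location)
    raw = model.D_joint.copy()
    floored = raw.copy()
    for loc, out in history:
        lik = A[out, :, loc]
        raw = raw * lik
        floored = floored * np.maximum(lik, LIKELIHOOD_FLOOR)
    if raw.max() == 0.0:
        raise InconsistentScanPathError(
            "observation history has zero likelihood under every latent state"
        )
    return floored / floored.sum()


def update_beliefs(
    model: SceneModel, beliefs: Beliefs, observation: tuple[str | int, str | int]
) -> Beliefs:
    """Condition beliefs on one (location, what-outcome) observation.

    Tokens or integer indices are accepted. Returns a new ``Beliefs``; the
    input is not mutated. Raises :class:`InconsistentScanPathError` when the
    accumulated history is impossible under every scene configuration (used
    by model inversion to reject malformed scan-path files).
    """
    loc, out = observation
    loc_i = LOC_INDEX[loc] if isinstance(loc, str) else int(loc)
    out_i = WHAT_INDEX[out] if isinstance(out, str) else int(out)
    history = beliefs.history + [(loc_i, out_i)]
    q = posterior_from_history(model, history)
    return Beliefs(q_joint=q, location=loc_i, history=history)


def action_targets(H: np.ndarray, current: int) -> np.ndarray:
    """Target location of each of the nine policies from ``current``.

    Policies 1-8 target the eight locations directly; policy 9 follows the
    heuristic map.
    """
    targets = np.arange(N_POLICIES)
    targets[8] = H[current]
    return targets


def epistemic_value(
    model: SceneModel, beliefs: Beliefs, action: int, H: np.ndarray | None = None
) -> float:
    """Expected Bayesian surprise of one policy's saccade (nats, >= 0).

    The expectation over predicted what-outcomes at the target location of
    the KL divergence between the updated and current posterior over the
    joint latents. The where-outcome is deterministic and contributes
    nothing.
    """
    if H is None:
        H = model.H
    target = int(action_targets(H, beliefs.location)[action])
    return float(_epistemic_for_targets(model, beliefs.q_joint, np.array([target]))[0])


def _epistemic_for_targets(
    model: SceneModel, q: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Vectorised epistemic value for a set of target locations."""
    A = model.A_joint[:, :, targets]  # (outcome, joint, n_targets)
    p_o = np.einsum("ojt,j->ot", A, q)  # predictive outcome distribution
    post = A * q[None, :, None]  # unnormalised posterior per outcome
    with np.errstate(divide="ignore", invalid="ignore"):
        post_n = np.where(p_o[:, None, :] > 0, post / p_o[:, None, :], 0.0)
        log_ratio = np.where(post_n > 0, np.log(post_n) - np.log(q)[None, :, None], 0.0)
    kl = (post_n * log_ratio).sum(axis=1)  # (outcome, n_targets)
    return np.maximum((p_o * kl).sum(axis=0), 0.0)


def pragmatic_value(
    model: SceneModel,
    prefs: Preferences,
    beliefs: Beliefs,
    action: int,
    tau: int,
    H: np.ndarray | None = None,
) -> float:
    """Expected utility of one policy's saccade at the next step (nats).

    ``tau`` is the current 1-based time step; the outcome lands at step
    ``tau + 1``, which must not exceed the horizon.
    """
    if tau + 1 > prefs.T:
        raise ValueError(f"step {tau + 1} exceeds the trial horizon T={prefs.T}")
    if H is None:
        H = model.H
    target = int(action_targets(H, beliefs.location)[action])
    p_o = model.A_joint[:, :, target] @ beliefs.q_joint
    return float(p_o @ prefs.C_what[:, tau] + prefs.C_where[target, tau])


@dataclass
class PolicyEvaluation:
    """Per-policy quantities entering policy selection (all in nats)."""

    E: np.ndarray
    F: np.ndarray
    G: np.ndarray
    epistemic: np.ndarray
    pragmatic: np.ndarray
    pi: np.ndarray
    beta: float


def policy_posterior(
    E: np.ndarray, F: np.ndarray, G: np.ndarray, beta: float
) -> np.ndarray:
    """Softmax posterior over policies: sigma(E - F - G / beta)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    logits = E - F - G / beta
    logits = logits - logits.max()
    p = np.exp(logits)
    return p / p.sum()


def evaluate_policies(
    model: SceneModel,
    prefs: Preferences,
    prior: PolicyPrior,
    beliefs: Beliefs,
    tau: int,
    beta: float,
    include_epistemic: bool = True,
) -> PolicyEvaluation:
    """Expected free energy and posterior over the nine one-step policies.

    ``G = -epistemic - pragmatic``; with ``include_epistemic=False`` the
    uncertainty-resolving term is removed and expected free energy reduces to
    a (negative) expected utility.
    """
    if tau + 1 > prefs.T:
        raise ValueError(f"step {tau + 1} exceeds the trial horizon T={prefs.T}")
    targets = action_targets(prior.H, beliefs.location)
    if include_epistemic:
        epi = _epistemic_for_targets(model, beliefs.q_joint, targets)
    else:
        epi = np.zeros(N_POLICIES)
    p_o = np.einsum("ojt,j->ot", model.A_joint[:, :, targets], beliefs.q_joint)
    prag = p_o.T @ prefs.C_what[:, tau] + prefs.C_where[targets, tau]
    G = -epi - prag
    F = np.zeros(N_POLICIES)  # past free energy is policy-independent here
    pi = policy_posterior(prior.E, F, G, beta)
    return PolicyEvaluation(
        E=prior.E.copy(), F=F, G=G, epistemic=epi, pragmatic=prag, pi=pi, beta=beta
    )


def select_action(
    pi: np.ndarray, mode: str = "sample", rng: np.random.Generator | None = None
) -> int:
    """Draw or pick a policy index from the policy posterior.

    ``sample`` draws from ``pi`` with the supplied generator; ``argmax``
    breaks ties toward the lowest policy index.
    """
    if mode == "argmax":
        return int(np.argmax(pi))
    if mode == "sample":
        if rng is None:
            raise ValueError("sample mode requires a seeded generator")
        return int(rng.choice(len(pi), p=pi / pi.sum()))
    raise ValueError(f"unknown selection mode: {mode!r}")
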