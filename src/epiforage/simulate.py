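"""Gaze-contingent task environment and agent-environment loops.

A trial starts at the central fixation; at each step the agent's policy
posterior selects a saccade. Looking at a quadrant reveals the object there;
looking at a choice location is the categorisation response and ends the
trial with right/wrong feedback. Scoring follows the task rules: +2 points
for a correct categorisation, -4 for an incorrect one, -4 for running out of
steps without choosing, and a stacking exploration cost of -0.25 * n for the
n-th distinct square attended (two squares cost -0.25 + -0.50 = -0.75).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generative_model import (
    PolicyPrior,
    Preferences,
    SceneModel,
    build_policy_prior,
    build_preferences,
    build_scene_layout,
    build_scene_model,
    heuristic_kernel,
)
from .inference import (
    evaluate_policies,
    initial_beliefs,
    select_action,
    update_beliefs,
)
from .labels import (
    CHOICE_IDX,
    CONTEXTS,
    FIX,
    LOCATIONS,
    LOC_INDEX,
    QUADRANTS,
)


@dataclass
class TrialRecord:
    """One trial's scan path, choice and score."""

    scene: tuple[str, bool, bool]
    path: list[tuple[int, str, str]]  # (step, location, what-outcome)
    choice: str | None
    feedback: str | None
    n_quadrants: int
    score_delta: float


@dataclass
class BlockSummary:
    """Aggregate behavioural measures over one block of trials."""

    mean_score_per_trial: float
    pct_correct: float
    mean_saccades_per_trial: float
    n_trials: int


@dataclass
class Agent:
    """A parameterised task model bundle: generative model, preferences,
    policy prior, and the precision of policy selection."""

    model: SceneModel
    prefs: Preferences
    prior: PolicyPrior
    beta: float
    include_epistemic: bool = True


def make_agent(
    ln_beta: float = 0.0,
    E_h: float = 0.0,
    ln_C_cor: float = 0.0,
    ln_C_q: float = 0.0,
    order: tuple[str, ...] | None = None,
    H: np.ndarray | None = None,
    T: int = 6,
    include_epistemic: bool = True,
    model: SceneModel | None = None,
) -> Agent:
    """Assemble an agent from the four subject-level parameters.

    The parameters live in log space: ``beta = exp(ln_beta)`` is the inverse
    precision of policy selection, ``E_h`` the log heuristic bias, and
    ``ln_C_cor`` / ``ln_C_q`` the log scaling coefficients on the what- and
    where-modality preferences.
    """
    if H is None:
        H = heuristic_kernel(order) if order is not None else heuristic_kernel()
    if model is None:
        model = build_scene_model(H=H, T=T)
    prefs = build_preferences(ln_C_cor, ln_C_q, T=T)
    prior = build_policy_prior(E_h, H)
    return Agent(
        model=model,
        prefs=prefs,
        prior=prior,
        beta=float(np.exp(ln_beta)),
        include_epistemic=include_epistemic,
    )


def sample_scene(rng: np.random.Generator) -> tuple[str, bool, bool]:
    """Uniform draw over the 12 scene configurations."""
    return (
        CONTEXTS[int(rng.integers(3))],
        bool(rng.integers(2)),
        bool(rng.integers(2)),
    )


def _emit_outcome(scene: tuple[str, bool, bool], location: int) -> str:
    """What the environment shows at ``location`` under ``scene``."""
    context, vflip, hflip = scene
    if location == FIX:
        return "NULL"
    if location in CHOICE_IDX:
        chosen = CONTEXTS[CHOICE_IDX.index(location)]
        return "RIGHT" if chosen == context else "WRONG"
    layout = build_scene_layout(context, vflip, hflip)
    return layout[LOCATIONS[location]]


def score_trial(record: TrialRecord) -> float:
    """Points earned on one trial under the task's scoring rules.

    Feedback is worth +2 (right) or -4 (wrong); a time-out (no choice within
    the horizon) also costs 4 points. Attending the n-th distinct square
    costs 0.25 * n, stacking cumulatively; revisits do not pay twice.
    """
    if record.feedback == "RIGHT":
        base = 2.0
    else:  # WRONG or time-out
        base = -4.0
    nq = record.n_quadrants
    return base - 0.25 * nq * (nq + 1) / 2.0


def run_trial(
    agent: Agent,
    scene: tuple[str, bool, bool],
    rng: np.random.Generator | None = None,
    mode: str = "sample",
    forced_locations: list[str] | None = None,
) -> TrialRecord:
    """Run one agent-environment loop on ``scene``.

    The loop alternates belief updating, policy evaluation and action
    selection until a choice location is sampled or the horizon ``T`` is
    reached. ``forced_locations`` replays a fixed sequence of saccade targets
    instead of selecting actions (used to reproduce worked trials).
    """
    model, T = agent.model, agent.model.T
    beliefs = initial_beliefs(model)
    beliefs = update_beliefs(model, beliefs, (FIX, "NULL"))
    path: list[tuple[int, str, str]] = [(1, "FIX", "NULL")]
    choice: str | None = None
    feedback: str | None = None
    visited: set[str] = set()
    for tau in range(1, T):
        if forced_locations is not None:
            if tau - 1 >= len(forced_locations):
                break
            target = LOC_INDEX[forced_locations[tau - 1]]
        else:
            ev = evaluate_policies(
                model,
                agent.prefs,
                agent.prior,
                beliefs,
                tau,
                agent.beta,
                include_epistemic=agent.include_epistemic,
            )
            action = select_action(ev.pi, mode=mode, rng=rng)
            target = int(agent.prior.H[beliefs.location]) if action == 8 else action
        outcome = _emit_outcome(scene, target)
        path.append((tau + 1, LOCATIONS[target], outcome))
        if target in CHOICE_IDX:
            choice = CONTEXTS[CHOICE_IDX.index(target)]
            feedback = outcome
            break
        if LOCATIONS[target] in QUADRANTS:
            visited.add(LOCATIONS[target])
        beliefs = update_beliefs(model, beliefs, (target, outcome))
    record = TrialRecord(
        scene=scene,
        path=path,
        choice=choice,
        feedback=feedback,
        n_quadrants=len(visited),
        score_delta=0.0,
    )
    record.score_delta = score_trial(record)
    return record


def saccade_count(record: TrialRecord) -> int:
    """Exploratory saccades before categorising (choice step excluded)."""
    return len(record.path) - 1 - (1 if record.choice is not None else 0)


def run_block(
    agent: Agent,
    rng: np.random.Generator,
    n_trials: int = 100,
    start_points: float = 100.0,
    mode: str = "sample",
) -> tuple[list[TrialRecord], BlockSummary]:
    """Simulate one block of trials and summarise performance."""
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    records = []
    points = start_points
    for _ in range(n_trials):
        rec = run_trial(agent, sample_scene(rng), rng=rng, mode=mode)
        points += rec.score_delta
        records.append(rec)
    summary = summarise_block(records)
    return records, summary


def summarise_block(records: list[TrialRecord]) -> BlockSummary:
    n = len(records)
    return BlockSummary(
        mean_score_per_trial=float(np.mean([r.score_delta for r in records])),
        pct_correct=100.0 * sum(r.feedback == "RIGHT" for r in records) / n,
        mean_saccades_per_trial=float(np.mean([saccade_count(r) for r in records])),
        n_trials=n,
    )
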