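"""Discrete generative model of the gaze-contingent scene-categorisation task.

The task is a partially observed Markov decision process with four hidden
factors — scene context (Flee/Feed/Wait), sampling location, and vertical and
horizontal flips of the scene — and two outcome modalities: *what* is seen
(null, bird, seed, cat, or right/wrong feedback) and *where* the agent is
looking. Scene categories are defined by relative object placement: every
scene contains a bird; in Flee scenes a cat is row-adjacent to it, in Feed
scenes a seed is row-adjacent, and in Wait scenes the seed sits on the same
diagonal. The two flip factors move this relative arrangement around the
grid, so the absolute quadrant contents must be inferred from fixations.

Base layouts place the bird at TL, with the cat or seed at TR (Flee/Feed) or
BR (Wait); a vertical flip swaps rows and a horizontal flip swaps columns.

Columns of all probability tables are indexed by the *prior* (current) state;
tables are column-stochastic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .labels import (
    CHOICE_IDX,
    CONTEXTS,
    FIX,
    LOCATIONS,
    LOC_INDEX,
    N_CONTEXTS,
    N_JOINT,
    N_LOCATIONS,
    N_POLICIES,
    N_WHAT,
    QUADRANTS,
    WHAT_INDEX,
    WHAT_OUTCOMES,
    joint_index,
)

#: quadrant positions as (row, col) on the 2x2 grid
_GRID = {"TL": (0, 0), "TR": (0, 1), "BL": (1, 0), "BR": (1, 1)}
_GRID_INV = {v: k for k, v in _GRID.items()}

#: default reading-like heuristic order (left-to-right, top-to-bottom)
READING_ORDER: tuple[str, ...] = ("TL", "TR", "BL", "BR")
#: clockwise exploration order
CLOCKWISE_ORDER: tuple[str, ...] = ("TL", "TR", "BR", "BL")


def build_scene_layout(context: str, vflip: bool, hflip: bool) -> dict[str, str]:
    """Quadrant contents for one scene configuration.

    Parameters
    ----------
    context : {"FLEE", "FEED", "WAIT"}
        Scene category.
    vflip, hflip : bool
        Vertical flip swaps the rows of the base layout; horizontal flip
        swaps the columns.

    Returns
    -------
    dict mapping each of ``TL, TR, BL, BR`` to an object token. Exactly one
    quadrant holds ``BIRD``; one holds ``CAT`` (Flee) or ``SEED``
    (Feed/Wait); the rest are ``NULL``.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context token: {context!r}")
    base = {"TL": "BIRD"}
    if context == "FLEE":
        base["TR"] = "CAT"
    elif context == "FEED":
        base["TR"] = "SEED"
    else:  # WAIT: seed on the same diagonal as the bird
        base["BR"] = "SEED"
    layout = {q: base.get(q, "NULL") for q in QUADRANTS}
    if vflip:
        layout = {
            _GRID_INV[(1 - _GRID[q][0], _GRID[q][1])]: obj for q, obj in layout.items()
        }
    if hflip:
        layout = {
            _GRID_INV[(_GRID[q][0], 1 - _GRID[q][1])]: obj for q, obj in layout.items()
        }
    return {q: layout[q] for q in QUADRANTS}


def all_layouts() -> dict[tuple[int, int, int], dict[str, str]]:
    """All 12 (context, vflip, hflip) layouts, keyed by index triples."""
    return {
        (c, v, h): build_scene_layout(CONTEXTS[c], bool(v), bool(h))
        for c in range(N_CONTEXTS)
        for v in (0, 1)
        for h in (0, 1)
    }


def build_likelihood(
    layouts: dict[tuple[int, int, int], dict[str, str]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood tables for both outcome modalities.

    ``A_what`` has shape (6 outcomes, 3 contexts, 8 locations, 2, 2) and is
    deterministic: fixation reveals nothing, a quadrant reveals the layout
    object there, and a choice location yields RIGHT feedback iff its
    category matches the context. ``A_where`` is the 8x8 identity: the agent
    knows where it is looking.
    """
    if layouts is None:
        layouts = all_layouts()
    A_what = np.zeros((N_WHAT, N_CONTEXTS, N_LOCATIONS, 2, 2))
    for (c, v, h), layout in layouts.items():
        A_what[WHAT_INDEX["NULL"], c, FIX, v, h] = 1.0
        for q in QUADRANTS:
            A_what[WHAT_INDEX[layout[q]], c, LOC_INDEX[q], v, h] = 1.0
        for ci, loc in enumerate(CHOICE_IDX):
            tok = "RIGHT" if ci == c else "WRONG"
            A_what[WHAT_INDEX[tok], c, loc, v, h] = 1.0
    A_where = np.eye(N_LOCATIONS)
    return A_what, A_where


def heuristic_kernel(order: tuple[str, ...] = READING_ORDER) -> np.ndarray:
    """Deterministic location->location map induced by a quadrant order.

    Fixation maps to the first quadrant, each quadrant to the next, the last
    quadrant to itself (absorbing), and choice locations to themselves, so a
    fixed-form policy can explore the scene but never emits a categorisation.
    """
    if sorted(order) != sorted(QUADRANTS):
        raise ValueError(f"order must be a permutation of the quadrants: {order!r}")
    H = np.arange(N_LOCATIONS)
    H[FIX] = LOC_INDEX[order[0]]
    for a, b in zip(order[:-1], order[1:]):
        H[LOC_INDEX[a]] = LOC_INDEX[b]
    H[LOC_INDEX[order[-1]]] = LOC_INDEX[order[-1]]
    return H


def build_transitions(H: np.ndarray) -> dict[str, np.ndarray]:
    """Action-conditioned transition tables.

    Only the sampling location is action-dependent: actions 1-8 are
    deterministic saccades to the corresponding location, and action 9
    follows the fixed-form (heuristic) state-action map ``H``. Context and
    flip factors do not change within a trial, so their tables are identity.
    """
    H = np.asarray(H, dtype=int)
    if H.shape != (N_LOCATIONS,):
        raise ValueError(f"H must map all {N_LOCATIONS} locations; got shape {H.shape}")
    if np.any((H < 0) | (H >= N_LOCATIONS)):
        raise ValueError("H contains an out-of-range location index")
    non_choice = [i for i in range(N_LOCATIONS) if i not in CHOICE_IDX]
    if np.any(np.isin(H[non_choice], CHOICE_IDX)):
        # choice locations are absorbing under H, but no exploration state
        # may reach one: fixed-form policies never emit a categorisation
        raise ValueError("heuristic map may not target a choice location")
    B_location = np.zeros((N_LOCATIONS, N_LOCATIONS, N_POLICIES))
    for a in range(N_LOCATIONS):
        B_location[a, :, a] = 1.0
    for cur in range(N_LOCATIONS):
        B_location[H[cur], cur, 8] = 1.0
    return {
        "B_location": B_location,
        "B_context": np.eye(N_CONTEXTS),
        "B_vflip": np.eye(2),
        "B_hflip": np.eye(2),
    }


@dataclass
class Preferences:
    """Log prior preferences (utilities, in nats) over outcomes at each step.

    ``C_what[:, t]`` and ``C_where[:, t]`` hold the utilities at time step
    ``t + 1`` (1-based steps; step 1 is the initial central fixation, whose
    utilities are zero). Correct feedback is worth +2 and incorrect feedback
    -4 points, scaled by ``k_cor``; remaining at a non-choice location at
    step tau costs 0.25 * (tau - 1) points, scaled by ``k_q``, so being
    undecided becomes increasingly costly.
    """

    C_what: np.ndarray
    C_where: np.ndarray
    k_cor: float
    k_q: float

    @property
    def T(self) -> int:
        return self.C_what.shape[1]


def build_preferences(ln_C_cor: float = 0.0, ln_C_q: float = 0.0, T: int = 6) -> Preferences:
    """Preference tables for a trial horizon of ``T`` steps.

    ``ln_C_cor`` and ``ln_C_q`` are log scaling coefficients multiplying the
    printed point values in the what and where modalities respectively; they
    tune the precision of the preferences.
    """
    if T < 2:
        raise ValueError("T must be at least 2: no post-fixation step exists")
    k_cor = float(np.exp(ln_C_cor))
    k_q = float(np.exp(ln_C_q))
    C_what = np.zeros((N_WHAT, T))
    C_where = np.zeros((N_LOCATIONS, T))
    for t in range(2, T + 1):
        C_what[WHAT_INDEX["RIGHT"], t - 1] = 2.0 * k_cor
        C_what[WHAT_INDEX["WRONG"], t - 1] = -4.0 * k_cor
        for loc in (FIX, *[LOC_INDEX[q] for q in QUADRANTS]):
            C_where[loc, t - 1] = -0.25 * (t - 1) * k_q
    return Preferences(C_what=C_what, C_where=C_where, k_cor=k_cor, k_q=k_q)


@dataclass
class PolicyPrior:
    """Log prior weights over the nine policies plus the heuristic map.

    The first eight entries of ``E`` (the location-targeting, potentially
    epistemic policies) are fixed at zero; the ninth is the heuristic bias
    ``E_h``, the log propensity to engage the fixed-form policy encoded by
    ``H``.
    """

    E: np.ndarray
    H: np.ndarray

    @property
    def E_h(self) -> float:
        return float(self.E[8])


def build_policy_prior(E_h: float = 0.0, H: np.ndarray | None = None) -> PolicyPrior:
    """Policy prior with heuristic bias ``E_h`` over heuristic map ``H``."""
    if H is None:
        H = heuristic_kernel()
    H = np.asarray(H, dtype=int)
    build_transitions(H)  # validates H
    E = np.zeros(N_POLICIES)
    E[8] = E_h
    return PolicyPrior(E=E, H=H)


@dataclass
class SceneModel:
    """The task's likelihoods, transitions and initial-state priors.

    All tables are column-stochastic with columns indexed by the current
    state. ``D`` holds the per-factor initial priors: context uniform, the
    location a point mass on central fixation, and each flip uniform.
    """

    A_what: np.ndarray
    A_where: np.ndarray
    B_location: np.ndarray
    B_context: np.ndarray
    B_vflip: np.ndarray
    B_hflip: np.ndarray
    D: dict[str, np.ndarray]
    T: int = 6
    labels: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "locations": LOCATIONS,
            "what_outcomes": WHAT_OUTCOMES,
            "contexts": CONTEXTS,
        }
    )

    @property
    def H(self) -> np.ndarray:
        """Heuristic map encoded in the ninth action's transition kernel."""
        return np.argmax(self.B_location[:, :, 8], axis=0)

    # -- joint-latent views -------------------------------------------------
    @property
    def A_joint(self) -> np.ndarray:
        """A_what reshaped to (outcome, 12 joint latent states, location)."""
        # (o, c, l, v, h) -> (o, c, v, h, l) -> (o, 12, l)
        return np.transpose(self.A_what, (0, 1, 3, 4, 2)).reshape(
            N_WHAT, N_JOINT, N_LOCATIONS
        )

    @property
    def D_joint(self) -> np.ndarray:
        """Initial prior over the 12 joint latent states (uniform)."""
        d = np.zeros(N_JOINT)
        for c in range(N_CONTEXTS):
            for v in (0, 1):
                for h in (0, 1):
                    d[joint_index(c, v, h)] = (
                        self.D["context"][c] * self.D["vflip"][v] * self.D["hflip"][h]
                    )
        return d

    def to_json(self) -> str:
        payload = {
            "labels": {k: list(v) for k, v in self.labels.items()},
            "T": self.T,
            "H": [LOCATIONS[i] for i in self.H],
            "tables": {
                name: {"shape": list(arr.shape), "data": arr.ravel().tolist()}
                for name, arr in [
                    ("A_what", self.A_what),
                    ("A_where", self.A_where),
                    ("B_location", self.B_location),
                    ("B_context", self.B_context),
                    ("B_vflip", self.B_vflip),
                    ("B_hflip", self.B_hflip),
                ]
            },
            "D": {k: v.tolist() for k, v in self.D.items()},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SceneModel":
        payload = json.loads(text)
        tables = {
            name: np.asarray(spec["data"]).reshape(spec["shape"])
            for name, spec in payload["tables"].items()
        }
        return cls(
            A_what=tables["A_what"],
            A_where=tables["A_where"],
            B_location=tables["B_location"],
            B_context=tables["B_context"],
            B_vflip=tables["B_vflip"],
            B_hflip=tables["B_hflip"],
            D={k: np.asarray(v) for k, v in payload["D"].items()},
            T=payload["T"],
            labels={k: tuple(v) for k, v in payload["labels"].items()},
        )


def build_scene_model(H: np.ndarray | None = None, T: int = 6) -> SceneModel:
    """Assemble the full generative model of the task."""
    if H is None:
        H = heuristic_kernel()
    A_what, A_where = build_likelihood()
    B = build_transitions(H)
    D_location = np.zeros(N_LOCATIONS)
    D_location[FIX] = 1.0
    D = {
        "context": np.full(N_CONTEXTS, 1.0 / N_CONTEXTS),
        "location": D_location,
        "vflip": np.full(2, 0.5),
        "hflip": np.full(2, 0.5),
    }
    return SceneModel(A_what=A_what, A_where=A_where, D=D, T=T, **B)
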