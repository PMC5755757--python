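import numpy as np
import pytest

from epiforage import build_scene_model
from epiforage.cohort import CohortConfig, generate_cohort

# ---------------------------------------------------------------------------
# Independent oracle: the 12 scene layouts written out by hand (base scenes
# place the bird top-left with the cat/seed row-adjacent for Flee/Feed and
# diagonal for Wait; vflip swaps rows, hflip swaps columns).
# ---------------------------------------------------------------------------
HAND_LAYOUTS = {
    # (context, vflip, hflip): {TL, TR, BL, BR}
    ("FLEE", 0, 0): {"TL": "BIRD", "TR": "CAT", "BL": "NULL", "BR": "NULL"},
    ("FLEE", 0, 1): {"TL": "CAT", "TR": "BIRD", "BL": "NULL", "BR": "NULL"},
    ("FLEE", 1, 0): {"TL": "NULL", "TR": "NULL", "BL": "BIRD", "BR": "CAT"},
    ("FLEE", 1, 1): {"TL": "NULL", "TR": "NULL", "BL": "CAT", "BR": "BIRD"},
    ("FEED", 0, 0): {"TL": "BIRD", "TR": "SEED", "BL": "NULL", "BR": "NULL"},
    ("FEED", 0, 1): {"TL": "SEED", "TR": "BIRD", "BL": "NULL", "BR": "NULL"},
    ("FEED", 1, 0): {"TL": "NULL", "TR": "NULL", "BL": "BIRD", "BR": "SEED"},
    ("FEED", 1, 1): {"TL": "NULL", "TR": "NULL", "BL": "SEED", "BR": "BIRD"},
    ("WAIT", 0, 0): {"TL": "BIRD", "TR": "NULL", "BL": "NULL", "BR": "SEED"},
    ("WAIT", 0, 1): {"TL": "NULL", "TR": "BIRD", "BL": "SEED", "BR": "NULL"},
    ("WAIT", 1, 0): {"TL": "NULL", "TR": "SEED", "BL": "BIRD", "BR": "NULL"},
    ("WAIT", 1, 1): {"TL": "SEED", "TR": "NULL", "BL": "NULL", "BR": "BIRD"},
}

CONTEXT_ORDER = ("FLEE", "FEED", "WAIT")


def exact_posterior_oracle(history):
    """Exact joint/marginal posterior over the 12 latent states by brute
    enumeration of the hand-written layouts (zero-likelihood states get the
    exp(-16) floor per observation, mirroring the documented log-floor)."""
    floor = np.exp(-16.0)
    keys = [
        (c, v, h) for c in CONTEXT_ORDER for v in (0, 1) for h in (0, 1)
    ]
    w = np.ones(12)
    for loc, out in history:
        for i, key in enumerate(keys):
            if loc == "FIX":
                lik = 1.0 if out == "NULL" else 0.0
            elif loc.startswith("CH_"):
                right = key[0] == loc[3:]
                lik = 1.0 if out == ("RIGHT" if right else "WRONG") else 0.0
            else:
                lik = 1.0 if HAND_LAYOUTS[key][loc] == out else 0.0
            w[i] *= max(lik, floor)
    p = w / w.sum()
    marg_c = np.array(
        [sum(p[i] for i, k in enumerate(keys) if k[0] == c) for c in CONTEXT_ORDER]
    )
    marg_v = np.array([sum(p[i] for i, k in enumerate(keys) if k[1] == v) for v in (0, 1)])
    marg_h = np.array([sum(p[i] for i, k in enumerate(keys) if k[2] == h) for h in (0, 1)])
    return p, marg_c, marg_v, marg_h


@pytest.fixture(scope="session")
def model():
    return build_scene_model()


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the study design's defaults (22 subjects x 5 blocks x 100
    trials, planted preference decays); shared across the slower tests."""
    return generate_cohort(CohortConfig(seed=7))
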