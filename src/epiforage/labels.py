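"""Token vocabularies and index conventions for the scene-categorisation task.

The display is a 2x2 grid sampled through gaze. The agent can occupy one of
eight locations: the central fixation cross, the four quadrants, or one of
three choice locations (looking at a choice location *is* the categorisation
response). Cues are drawn from a six-token ``what`` vocabulary; the scene
context is one of three categories defined by the relative placement of a
bird, a cat and a seed.
"""

from __future__ import annotations

LOCATIONS: tuple[str, ...] = (
    "FIX", "TL", "TR", "BL", "BR", "CH_FLEE", "CH_FEED", "CH_WAIT",
)
WHAT_OUTCOMES: tuple[str, ...] = ("NULL", "BIRD", "SEED", "CAT", "RIGHT", "WRONG")
CONTEXTS: tuple[str, ...] = ("FLEE", "FEED", "WAIT")

QUADRANTS: tuple[str, ...] = ("TL", "TR", "BL", "BR")

LOC_INDEX = {t: i for i, t in enumerate(LOCATIONS)}
WHAT_INDEX = {t: i for i, t in enumerate(WHAT_OUTCOMES)}
CONTEXT_INDEX = {t: i for i, t in enumerate(CONTEXTS)}

FIX = LOC_INDEX["FIX"]
QUADRANT_IDX: tuple[int, ...] = tuple(LOC_INDEX[q] for q in QUADRANTS)
CHOICE_IDX: tuple[int, ...] = tuple(LOC_INDEX[f"CH_{c}"] for c in CONTEXTS)

N_LOCATIONS = len(LOCATIONS)
N_WHAT = len(WHAT_OUTCOMES)
N_CONTEXTS = len(CONTEXTS)
N_POLICIES = 9  # 8 location-targeting policies + 1 fixed-form heuristic

#: number of joint latent configurations: context x vflip x hflip
N_JOINT = N_CONTEXTS * 2 * 2


def choice_for_context(context: str) -> str:
    """Choice-location token matching a context token."""
    return f"CH_{context}"


def context_of_choice(location: str) -> str:
    """Context token a choice location reports; raises for non-choice tokens."""
    if not location.startswith("CH_"):
        raise ValueError(f"not a choice location: {location!r}")
    return location[3:]


def joint_index(context: int, vflip: int, hflip: int) -> int:
    """Flat index of a joint latent state (context-major, then vflip, hflip)."""
    return context * 4 + vflip * 2 + hflip


def joint_state(index: int) -> tuple[int, int, int]:
    """Inverse of :func:`joint_index`."""
    return index // 4, (index % 4) // 2, index % 2
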