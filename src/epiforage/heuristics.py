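"""Fixed-form exploration orders and heuristic-consistency scoring.

Because the four quadrants are not revisited, there are 4! = 24 possible
fixed orders of exploring the scene. Each is treated as a fixed-form
(state-action) policy: a deterministic map from the current location to the
next, independent of beliefs. A subject's heuristic map is estimated from
the empirical transition frequencies of their saccade sequences, and each
trial's scan path is scored for consistency with each order (a trial is
consistent with an order when its quadrant visit sequence is a prefix of
that order — short paths can therefore be explained by several heuristics at
once).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .generative_model import heuristic_kernel
from .labels import CHOICE_IDX, LOC_INDEX, N_LOCATIONS, QUADRANTS


@dataclass(frozen=True)
class HeuristicOrder:
    """A quadrant permutation and its induced location->location kernel."""

    order: tuple[str, ...]
    map: tuple[int, ...]

    @property
    def H(self) -> np.ndarray:
        return np.asarray(self.map, dtype=int)


def enumerate_fixed_orders() -> list[HeuristicOrder]:
    """All 24 quadrant orders, sorted lexicographically by location index."""
    orders = []
    for perm in itertools.permutations(QUADRANTS):
        orders.append(HeuristicOrder(order=perm, map=tuple(heuristic_kernel(perm))))
    return orders


def estimate_heuristic_map(scanpaths: Iterable[Sequence[str]]) -> np.ndarray:
    """Most frequent next location from each location, over all saccade sequences.

    ``scanpaths`` is an iterable of location-token sequences (one per trial,
    starting at FIX). Transitions into choice locations are excluded so the
    estimated map is a valid heuristic kernel (fixed-form policies explore
    but never categorise). Ties go to the lowest location index; locations
    never left map to themselves.
    """
    counts = np.zeros((N_LOCATIONS, N_LOCATIONS))
    n_transitions = 0
    for path in scanpaths:
        for a, b in zip(path[:-1], path[1:]):
            j = LOC_INDEX[b]
            if j in CHOICE_IDX:
                continue
            counts[LOC_INDEX[a], j] += 1
            n_transitions += 1
    if n_transitions == 0:
        raise ValueError("no location transitions observed in the scan paths")
    H = np.arange(N_LOCATIONS)
    for loc in range(N_LOCATIONS):
        if counts[loc].sum() > 0:
            H[loc] = int(np.argmax(counts[loc]))  # argmax takes the lowest index on ties
    return H


def quadrant_sequence(path: Sequence[str]) -> tuple[str, ...]:
    """Quadrant visits along a path, choice/fixation steps stripped and
    consecutive repeats collapsed."""
    seq: list[str] = []
    for loc in path:
        if loc in QUADRANTS and (not seq or seq[-1] != loc):
            seq.append(loc)
    return tuple(seq)


def heuristic_consistency(
    scanpaths: Iterable[Sequence[str]],
    orders: list[HeuristicOrder] | None = None,
) -> tuple[dict[tuple[str, ...], float], tuple[HeuristicOrder, float], int]:
    """Per-order consistency frequencies over trials, and the favourite.

    A trial accords with an order when its quadrant sequence is a prefix of
    the order, so per-order frequencies can sum to more than 1 across
    orders. Trials with no quadrant fixations (an immediate choice) are
    consistent with every order; they are excluded from the denominator and
    their count is returned for flagging.

    Returns ``(frequencies, (favourite_order, favourite_frequency),
    n_zero_quadrant_trials)``.
    """
    if orders is None:
        orders = enumerate_fixed_orders()
    sequences = [quadrant_sequence(p) for p in scanpaths]
    n_zero = sum(1 for s in sequences if len(s) == 0)
    scored = [s for s in sequences if len(s) > 0]
    if not scored:
        raise ValueError("no trials with quadrant fixations to score")
    freqs: dict[tuple[str, ...], float] = {}
    for ho in orders:
        hits = sum(1 for s in scored if s == ho.order[: len(s)])
        freqs[ho.order] = hits / len(scored)
    fav = max(orders, key=lambda ho: freqs[ho.order])
    return freqs, (fav, freqs[fav.order]), n_zero
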