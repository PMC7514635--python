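"""Shared fixtures: brute-force oracles and small exact tables.

The brute-force counter below enumerates *all* direction strings and
filters them through the reference walk validator — it shares no code with
the incremental DFS kernels it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from trailzeros import (
    CountTable,
    DIRECTIONS,
    LatticeWalk,
    ModelWeights,
    WalkError,
    count_features,
    enumerate_trails,
)


def brute_force_counts(weights: ModelWeights, n_max: int) -> dict:
    """Exact counts by exhaustive iteration over all 4^N direction strings."""
    counts: dict[tuple, int] = {}
    for n in range(1, n_max + 1):
        for combo in itertools.product(DIRECTIONS, repeat=n):
            try:
                walk = LatticeWalk(combo, surface=weights.surface)
                feats = count_features(walk, weights)
            except WalkError:
                continue
            key = feats.as_key()
            counts[key] = counts.get(key, 0) + 1
    return counts


def random_walk(weights: ModelWeights, n_max: int, rng) -> LatticeWalk:
    """Grow a random legal walk (uniform atmosphere choice), for properties."""
    from trailzeros import legal_continuations

    walk = LatticeWalk((), surface=weights.surface)
    for _ in range(n_max):
        atmosphere = sorted(legal_continuations(walk, weights), key=lambda d: d.name)
        if not atmosphere:
            break
        walk = walk.extended(atmosphere[rng.integers(len(atmosphere))])
    return walk


@pytest.fixture(scope="session")
def isat():
    return ModelWeights.isat()


@pytest.fixture(scope="session")
def exact_isat_n10():
    """Exact bulk ISAT table to N=10 (oracle for sampling and zeros)."""
    return enumerate_trails(ModelWeights.isat(), 10)


@pytest.fixture(scope="session")
def exact_surface_n8():
    """Exact surface-mode ISAT table to N=8 (all features resolved)."""
    return enumerate_trails(ModelWeights.isat(surface=True), 8)


@pytest.fixture(scope="session")
def brute_isat_n6(isat):
    return brute_force_counts(isat, 6)
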