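"""Shared fixtures: sampled community pools reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import glvec as g
from glvec.equilibria import sample_stable_subsets

# (mu, sigma) points inside the emergent-coexistence regime of an 80-species
# pool; used wherever tests need a population of stable communities.
EC_GRID = [(-0.5, 0.3), (-0.5, 0.45), (-0.75, 0.3), (-0.75, 0.45),
           (-0.75, 0.6), (-1.0, 0.45), (-1.0, 0.6)]


@pytest.fixture(scope="session")
def grid_communities():
    """Stable communities subset-sampled across the EC-regime grid.

    Returns a list of (community, mu, sigma) triples spanning sizes 3..12.
    """
    rng = np.random.default_rng(20240901)
    out = []
    for mu, sigma in EC_GRID:
        matrix = g.sample_matrix(
            g.EnsembleSpec(S=80, mu=mu, sigma=sigma), seed=int(rng.integers(2**31))
        )
        comms = sample_stable_subsets(
            matrix, list(range(3, 13)), 400, seed=int(rng.integers(2**31))
        )
        out.extend((c, mu, sigma) for c in comms)
    return out


@pytest.fixture(scope="session")
def ec_communities(grid_communities):
    """The subset of grid communities that are EC states."""
    return [
        (c, mu, sigma)
        for c, mu, sigma in grid_communities
        if g.ec_report(c).is_ec
    ]


@pytest.fixture(scope="session")
def small_pool():
    """A seeded 8-species pool small enough for exhaustive enumeration."""
    return g.sample_matrix(g.EnsembleSpec(S=8, mu=-0.8, sigma=0.5), seed=77)
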