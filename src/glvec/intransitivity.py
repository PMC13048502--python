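"""Competitive hierarchy and intransitivity of exclusion networks.

Every excluding pair of a community defines a directed contest: the species
that would be competitively excluded in isolation loses, and the edge points
winner → loser.  When exactly one of the two coefficients is exclusionary
(A*_ij < −1 ≤ A*_ji), species j excludes species i.  When both are
(a bistable pair), the co-culture winner is not defined by the model, so the
orientation is an explicit rule: ``stronger_effect`` (default) lets the
larger-magnitude coefficient win — the harder-hit species loses, ties going
to the lower-indexed species — while ``unoriented`` leaves such pairs out of
rank and low-rank-exclusion counts but keeps them as triplet members.

Metrics:

* rank of a species: (wins − losses) / (S* − 1);
* LRE (low-rank exclusion) fraction: exclusions where the winner has a
  strictly lower rank than the loser, over all oriented exclusions; the
  corrected variant is reported only for communities with at least four
  exclusions (smaller communities cannot express an upset);
* RPS fraction: among species trios whose three pairs are all excluding,
  the fraction forming a directed 3-cycle (rock-paper-scissors).  Orienting
  each edge by a fair coin makes 2 of the 8 orientations cyclic, so the null
  expectation is exactly 0.25.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityState
from .ensembles import ConfigurationError, EnsembleSpec, sample_matrix
from .ec_metrics import ec_report

__all__ = [
    "ExclusionGraph",
    "IntransitivityReport",
    "NULL_RPS",
    "exclusion_digraph",
    "ranks_and_lre",
    "rps_fraction",
    "intransitivity_report",
    "intransitivity_scan",
]

NULL_RPS = 0.25  # 2 cyclic orientations of the 8 possible on a triangle


@dataclass
class ExclusionGraph:
    nodes: np.ndarray  # local indices 0..S*-1
    edges: list[tuple[int, int]]  # winner -> loser
    bistable_pairs: list[tuple[int, int]]
    unoriented_pairs: list[tuple[int, int]]
    direction_rule: str

    @property
    def n_exclusions(self) -> int:
        return len(self.edges) + len(self.unoriented_pairs)


def exclusion_digraph(
    community: CommunityState, direction_rule: str = "stronger_effect"
) -> ExclusionGraph:
    """Build the winner→loser digraph of a verified community."""
    if direction_rule not in ("stronger_effect", "unoriented"):
        raise ConfigurationError(f"unknown direction rule {direction_rule!r}")
    A = community.A_star
    n = community.S_star
    edges: list[tuple[int, int]] = []
    bistable: list[tuple[int, int]] = []
    unoriented: list[tuple[int, int]] = []
    for i, j in itertools.combinations(range(n), 2):
        hit_i = A[i, j] < -1.0  # j excludes i
        hit_j = A[j, i] < -1.0  # i excludes j
        if not (hit_i or hit_j):
            continue
        if hit_i and hit_j:
            bistable.append((i, j))
            if direction_rule == "unoriented":
                unoriented.append((i, j))
            elif abs(A[i, j]) >= abs(A[j, i]):
                # species i is hit at least as hard -> i loses (tie: lower
                # index wins, i.e. edge i -> j would need |A_ji| > |A_ij|)
                edges.append((j, i))
            else:
                edges.append((i, j))
        elif hit_i:
            edges.append((j, i))
        else:
            edges.append((i, j))
    return ExclusionGraph(
        nodes=np.arange(n),
        edges=edges,
        bistable_pairs=bistable,
        unoriented_pairs=unoriented,
        direction_rule=direction_rule,
    )


@dataclass
class IntransitivityReport:
    ranks: np.ndarray
    lre_fraction_raw: float | None
    lre_fraction_corrected: float | None  # None unless >= 4 exclusions
    rps_fraction: float | None  # None when no fully-excluding triplet
    n_exclusions: int
    n_triplets: int
    null_rps: float = NULL_RPS


def ranks_and_lre(graph: ExclusionGraph) -> tuple[np.ndarray, float | None, float | None]:
    """Per-species ranks and the raw / corrected low-rank-exclusion fractions."""
    n = graph.nodes.size
    wins = np.zeros(n)
    losses = np.zeros(n)
    for w, l in graph.edges:
        wins[w] += 1
        losses[l] += 1
    denom = max(n - 1, 1)
    ranks = (wins - losses) / denom
    if not graph.edges:
        return ranks, None, None
    upsets = sum(1 for w, l in graph.edges if ranks[w] < ranks[l])
    raw = upsets / len(graph.edges)
    corrected = raw if graph.n_exclusions >= 4 else None
    return ranks, raw, corrected


def rps_fraction(graph: ExclusionGraph) -> tuple[float | None, int]:
    """Fraction of fully-excluding trios forming a directed 3-cycle."""
    n = graph.nodes.size
    winner = {}
    for w, l in graph.edges:
        winner[(w, l)] = w
        winner[(l, w)] = w
    excl_pairs = set()
    for w, l in graph.edges:
        excl_pairs.add((min(w, l), max(w, l)))
    for i, j in graph.unoriented_pairs:
        excl_pairs.add((min(i, j), max(i, j)))
    n_triplets = 0
    n_rps = 0
    for a, b, c in itertools.combinations(range(n), 3):
        if not (
            (a, b) in excl_pairs and (a, c) in excl_pairs and (b, c) in excl_pairs
        ):
            continue
        n_triplets += 1
        if any(p in {(a, b), (a, c), (b, c)} for p in graph.unoriented_pairs):
            continue  # unoriented edge: cannot certify a cycle
        # cyclic iff every node has exactly one win within the trio
        trio_wins = {a: 0, b: 0, c: 0}
        for u, v in ((a, b), (a, c), (b, c)):
            trio_wins[winner[(u, v)]] += 1
        if set(trio_wins.values()) == {1}:
            n_rps += 1
    if n_triplets == 0:
        return None, 0
    return n_rps / n_triplets, n_triplets


def intransitivity_report(
    community: CommunityState, direction_rule: str = "stronger_effect"
) -> IntransitivityReport:
    graph = exclusion_digraph(community, direction_rule)
    ranks, raw, corrected = ranks_and_lre(graph)
    rps, n_trip = rps_fraction(graph)
    return IntransitivityReport(
        ranks=ranks,
        lre_fraction_raw=raw,
        lre_fraction_corrected=corrected,
        rps_fraction=rps,
        n_exclusions=graph.n_exclusions,
        n_triplets=n_trip,
    )


def _reshuffled_community(
    community: CommunityState, rng: np.random.Generator
) -> CommunityState:
    """Control: permute the off-diagonal elements of A* (structure destroyed,
    element distribution kept).  Used as a metric control only — feasibility
    and stability of the shuffled matrix are not re-imposed."""
    A = community.A_star.copy()
    n = A.shape[0]
    mask = ~np.eye(n, dtype=bool)
    vals = A[mask]
    A[mask] = rng.permutation(vals)
    shuffled = CommunityState.__new__(CommunityState)
    shuffled.pool_indices = community.pool_indices.copy()
    shuffled.x_star = community.x_star.copy()
    shuffled.A_star = A
    shuffled.r_star = community.r_star.copy()
    shuffled.feasible = True
    shuffled.stable = True
    shuffled.origin = "sampled"
    return shuffled


def intransitivity_scan(
    S: int,
    mu: float,
    sigma: float,
    structures: list[str],
    sizes: list[int],
    n_communities: int,
    seed: int | None = None,
    max_subset_draws: int = 200_000,
    direction_rule: str = "stronger_effect",
) -> pd.DataFrame:
    """Sample stable EC communities per structure and size; summarize LRE/RPS.

    ``reshuffled`` takes each random-structure community and permutes the
    off-diagonal elements of its A* before measuring.  Cells where no EC
    community was found within the draw budget are reported with
    ``n_communities = 0`` and NaN summaries.
    """
    from .equilibria import community_from_subset

    allowed = {"random", "reshuffled", "triangular", "k_correlated", "crossfeeding"}
    bad = set(structures) - allowed
    if bad:
        raise ConfigurationError(f"unknown scan structures {sorted(bad)}")
    if n_communities < 1:
        raise ConfigurationError(f"n_communities must be >= 1, got {n_communities}")
    ss = np.random.SeedSequence(seed)
    rows = []
    needs_random = [s for s in structures if s in ("random", "reshuffled")]
    plain = [s for s in structures if s not in ("random", "reshuffled")]
    for size in sizes:
        found_random: list[CommunityState] = []
        scan_items = ([("random", None)] if needs_random else []) + [
            (s, None) for s in plain
        ]
        for structure, _ in scan_items:
            rng = np.random.default_rng(ss.spawn(1)[0])
            found: list[CommunityState] = []
            draws = 0
            while len(found) < n_communities and draws < max_subset_draws:
                matrix = sample_matrix(
                    EnsembleSpec(S=S, mu=mu, sigma=sigma, structure=structure),
                    seed=int(rng.integers(2**31 - 1)),
                )
                for _ in range(max(1, min(2000, max_subset_draws - draws))):
                    draws += 1
                    idx = rng.choice(S, size=size, replace=False)
                    comm = community_from_subset(matrix, idx)
                    if comm is not None and ec_report(comm).is_ec:
                        found.append(comm)
                        if len(found) >= n_communities:
                            break
            if structure == "random":
                found_random = found
            targets = [structure] if structure in structures else []
            for tag in targets:
                rows.append(
                    _summarize(tag, size, found, direction_rule)
                )
        if "reshuffled" in structures:
            rng = np.random.default_rng(ss.spawn(1)[0])
            shuffled = [_reshuffled_community(c, rng) for c in found_random]
            rows.append(_summarize("reshuffled", size, shuffled, direction_rule))
    return pd.DataFrame(rows)


def _summarize(
    structure: str, size: int, comms: list[CommunityState], rule: str
) -> dict:
    """Per-community means/sds plus pooled (count-level) fractions.

    The pooled fractions aggregate RPS triplets and upset edges across all
    communities of the cell; they are the low-variance estimator when single
    communities contribute only a handful of triplets."""
    lres = []
    rpss = []
    n4 = 0
    n_rps = n_trip = 0
    n_upsets = n_edges4 = 0
    for c in comms:
        graph = exclusion_digraph(c, rule)
        ranks, raw, corrected = ranks_and_lre(graph)
        rps, n_t = rps_fraction(graph)
        if corrected is not None:
            lres.append(corrected)
            n4 += 1
            n_upsets += sum(1 for w, l in graph.edges if ranks[w] < ranks[l])
            n_edges4 += len(graph.edges)
        if rps is not None:
            rpss.append(rps)
            n_rps += round(rps * n_t)
            n_trip += n_t
    return {
        "structure": structure,
        "S_star": size,
        "n_communities": len(comms),
        "mean_lre": float(np.mean(lres)) if lres else np.nan,
        "sd_lre": float(np.std(lres)) if lres else np.nan,
        "mean_rps": float(np.mean(rpss)) if rpss else np.nan,
        "sd_rps": float(np.std(rpss)) if rpss else np.nan,
        "pooled_lre": n_upsets / n_edges4 if n_edges4 else np.nan,
        "pooled_rps": n_rps / n_trip if n_trip else np.nan,
        "n_triplets": n_trip,
        "n_with_4plus_exclusions": n4,
    }
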