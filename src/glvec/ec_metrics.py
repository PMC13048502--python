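"""Emergent-coexistence detection and its analytic boundaries.

Species *i* and *j* form an *excluding pair* when at least one of the two
rescaled coefficients is below −1 (competition stronger than
self-regulation), so the pair cannot coexist stably in isolation.  An *EC
state* is a stable community of at least three species containing at least
one excluding pair; a two-species stable state can never hold one, because
its own stability forbids exclusionary interactions.

Analytic pieces implemented here, all functions of the pool statistics
(mu, sigma) and pool size S with Phi the standard normal CDF:

* probability that the pool holds at least one exclusionary element,
  ``P = 1 - (1 - Phi(-(1+mu)/sigma))^(S(S-1))`` — its sharp 0→1 transition
  in sigma gives the lower EC-regime boundary sigma_1c(mu);
* probability that at least one pair is mutually non-exclusionary,
  ``1 - (1 - q)^(S(S-1)/2)`` with ``q = (1 - Phi(-(1+mu)/sigma))^2`` — for
  mean competition beyond self-regulation (mu < -1) this transitions from 0
  to 1 as heterogeneity grows, and the crossing gives the second boundary
  sigma_2c(mu) separating the pure competitive-exclusion regime from the EC
  regime;
* the minimum EC fraction ``2 / (S*(S*-1))`` (one pair of all pairs);
* the decaying maximum-fraction envelope combining a moderate-size
  maximum-diversity estimate with the pool fraction of excluding pairs
  ``f_max = 1 - q``.

The maximum-diversity estimate ``S*_max(mu, sigma)`` lives behind the single
function :func:`max_stable_diversity` so a refined closed form can be swapped
in.  The default treats the multistability regime's stable states as (near-)
cliques of the pairwise-coexistence graph: with pair-coexistence probability
q, the clique number of an Erdős–Rényi graph on S vertices concentrates at
``2 ln S / ln(1/q)``, which we round to the nearest integer and cap at S.
This reproduces the decaying envelope and yields a pool excluding-pair
fraction of ~60% at a predicted maximum diversity of 10 for an 80-species
pool.  It is a heuristic in two ways: stable states can be slightly larger
than cliques (they may contain excluding pairs — that is the point of EC),
and the bound assumes surviving communities are no more competitive than the
pool, so rare exceedances of the envelope are expected and tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .community import CommunityState, StateError
from .ensembles import ConfigurationError

__all__ = [
    "ECReport",
    "RegimeBoundaries",
    "is_excluding_pair",
    "excluding_pair_count",
    "ec_report",
    "p_exclusionary_element",
    "p_coexisting_pair_exists",
    "regime_boundaries",
    "min_excluding_fraction",
    "max_stable_diversity",
    "max_excluding_fraction_bound",
    "envelope_curve",
]

EXCLUSION_LEVEL = -1.0  # strict inequality: exactly -1 is not exclusionary


def is_excluding_pair(a_ij: float, a_ji: float) -> bool:
    """True iff at least one of the two directed coefficients is < -1."""
    if not (np.isfinite(a_ij) and np.isfinite(a_ji)):
        raise ValueError("interaction coefficients must be finite")
    return bool(a_ij < EXCLUSION_LEVEL or a_ji < EXCLUSION_LEVEL)


def excluding_pair_count(A_star: np.ndarray) -> int:
    """Number of unordered pairs with at least one exclusionary coefficient."""
    A = np.asarray(A_star, dtype=float)
    excl = (A < EXCLUSION_LEVEL) | (A.T < EXCLUSION_LEVEL)
    return int(np.triu(excl, k=1).sum())


@dataclass
class ECReport:
    S_star: int
    n_excluding_pairs: int
    fraction_excluding: float
    is_ec: bool


def ec_report(community: CommunityState) -> ECReport:
    """Count excluding pairs and flag EC (requires S* >= 3 and >= 1 pair)."""
    if not community.verified:
        raise StateError("community must be verified feasible and stable")
    n = community.S_star
    n_pairs = n * (n - 1) // 2
    n_excl = excluding_pair_count(community.A_star) if n >= 2 else 0
    frac = n_excl / n_pairs if n_pairs else 0.0
    return ECReport(
        S_star=n,
        n_excluding_pairs=n_excl,
        fraction_excluding=frac,
        is_ec=bool(n >= 3 and n_excl >= 1),
    )


# ---------------------------------------------------------------------------
# Pool-level probabilities and regime boundaries
# ---------------------------------------------------------------------------

def _p_single(mu: float | np.ndarray, sigma: float | np.ndarray) -> np.ndarray:
    """P(A_ij < -1) for one Gaussian off-diagonal element."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = -(1.0 + mu) / sigma
    p = norm.cdf(z)
    return np.where(sigma == 0, np.where(mu < -1.0, 1.0, 0.0), p)


def p_exclusionary_element(mu: float, sigma: float, S: int) -> float:
    """P(at least one of the S(S-1) pool elements is exclusionary)."""
    p = _p_single(mu, sigma)
    n = S * (S - 1)
    # log-space for numerical honesty at tiny p and large n
    with np.errstate(divide="ignore"):
        return float(-np.expm1(n * np.log1p(-np.clip(p, 0.0, 1.0))))


def p_coexisting_pair_exists(mu: float, sigma: float, S: int) -> float:
    """P(at least one pair is mutually non-exclusionary)."""
    p = _p_single(mu, sigma)
    q = (1.0 - p) ** 2
    n_pairs = S * (S - 1) // 2
    with np.errstate(divide="ignore"):
        if q <= 0:
            return 0.0
        return float(-np.expm1(n_pairs * np.log1p(-min(float(q), 1.0))))


@dataclass
class RegimeBoundaries:
    mu_grid: np.ndarray
    sigma1c: np.ndarray  # NaN where no crossing on the search interval
    sigma2c: np.ndarray
    S: int
    crossing_level: float


def _bisect_increasing(f, lo: float, hi: float, level: float, it: int = 80) -> float:
    for _ in range(it):
        mid = 0.5 * (lo + hi)
        if f(mid) >= level:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def regime_boundaries(
    S: int,
    mu_grid: np.ndarray,
    crossing_level: float = 0.5,
    sigma_max: float = 1.0,
) -> RegimeBoundaries:
    """Locate the sharp transitions bounding the EC regime in sigma.

    ``sigma1c(mu)``: smallest sigma at which exclusionary elements appear in
    the pool with probability >= ``crossing_level``.  ``sigma2c(mu)``:
    smallest sigma at which at least one mutually-coexisting pair (able to
    sustain an excluded third species) exists with probability >=
    ``crossing_level``; it is 0 for mu >= -1, where coexisting pairs are
    essentially certain at any heterogeneity, and grows as mean competition
    strengthens past self-regulation.  A boundary with no crossing on
    (0, sigma_max] is reported as NaN, not an exception.
    """
    if S < 3:
        raise ConfigurationError(f"S must be >= 3, got {S}")
    if not 0.0 < crossing_level < 1.0:
        raise ConfigurationError("crossing_level must lie in (0, 1)")
    mu_grid = np.atleast_1d(np.asarray(mu_grid, dtype=float))
    if not np.all(np.isfinite(mu_grid)):
        raise ConfigurationError("mu_grid must be finite")
    s1 = np.full(mu_grid.shape, np.nan)
    s2 = np.full(mu_grid.shape, np.nan)
    eps = 1e-12
    for k, mu in enumerate(mu_grid):
        f1 = lambda s: p_exclusionary_element(mu, s, S)  # noqa: E731
        if mu < -1.0 or f1(eps) >= crossing_level:
            s1[k] = 0.0
        elif f1(sigma_max) >= crossing_level:
            s1[k] = _bisect_increasing(f1, eps, sigma_max, crossing_level)
        f2 = lambda s: p_coexisting_pair_exists(mu, s, S)  # noqa: E731
        if mu >= -1.0 or f2(eps) >= crossing_level:
            s2[k] = 0.0
        elif f2(sigma_max) >= crossing_level:
            # f2 increases with sigma for mu < -1: find the crossing
            s2[k] = _bisect_increasing(f2, eps, sigma_max, crossing_level)
        # else: no coexisting pair within reach on (0, sigma_max] -> NaN
    return RegimeBoundaries(mu_grid, s1, s2, S, crossing_level)


# ---------------------------------------------------------------------------
# Minimum and maximum excluding-pair fractions
# ---------------------------------------------------------------------------

def min_excluding_fraction(S_star: int) -> float:
    """One excluding pair over all pairs, 2/(S*(S*-1)); defined for S* >= 3."""
    if S_star < 3:
        raise ConfigurationError(f"EC is undefined below 3 species, got {S_star}")
    return 2.0 / (S_star * (S_star - 1))


def max_stable_diversity(mu: float, sigma: float, pool_size: int = 80) -> int:
    """Moderate-size estimate of the largest stable community given (mu, sigma).

    Clique-number estimate of the pairwise-coexistence graph (see module
    docstring); the single swap point for a refined maximum-diversity
    formula.
    """
    if sigma < 0:
        raise ConfigurationError(f"sigma must be >= 0, got {sigma}")
    p = float(_p_single(mu, sigma))
    q = (1.0 - p) ** 2
    if q <= 0.0:
        return 1
    if q >= 1.0:
        return pool_size
    omega = 2.0 * np.log(pool_size) / np.log(1.0 / q)
    return int(min(pool_size, max(1, round(omega))))


def max_excluding_fraction_bound(
    mu: float, sigma: float, pool_size: int = 80
) -> tuple[int, float]:
    """(S*_max, f_max) point of the analytic envelope for one (mu, sigma).

    ``f_max = 1 - (1 - Phi(-(1+mu)/sigma))^2`` is the pool probability that a
    pair carries at least one exclusionary coefficient; the envelope assumes
    surviving communities are no more competitive than their pool.
    """
    if sigma < 0:
        raise ConfigurationError(f"sigma must be >= 0, got {sigma}")
    p = float(_p_single(mu, sigma))
    f_max = 1.0 - (1.0 - p) ** 2
    return max_stable_diversity(mu, sigma, pool_size), f_max


def envelope_curve(
    mu_grid: np.ndarray,
    sigma_grid: np.ndarray,
    pool_size: int = 80,
) -> dict[int, float]:
    """Sweep the grid; per predicted maximum diversity, the largest f_max.

    Returns a mapping S*_max -> max fraction over grid points predicting
    exactly that maximum diversity (the red-dashed envelope as a table).
    """
    mu = np.asarray(mu_grid, dtype=float)[:, None]
    sigma = np.asarray(sigma_grid, dtype=float)[None, :]
    p = _p_single(np.broadcast_to(mu, (mu.size, sigma.size)),
                  np.broadcast_to(sigma, (mu.size, sigma.size)))
    q = (1.0 - p) ** 2
    f = 1.0 - q
    with np.errstate(divide="ignore"):
        omega = 2.0 * np.log(pool_size) / np.log(1.0 / q)
    s_max = np.where(q <= 0.0, 1, np.where(q >= 1.0, pool_size,
                     np.clip(np.round(omega), 1, pool_size))).astype(int)
    valid = (sigma > 0) & (s_max >= 3)
    out: dict[int, float] = {}
    for s, fv in zip(s_max[valid].ravel(), f[valid].ravel()):
        if fv > out.get(int(s), -1.0):
            out[int(s)] = float(fv)
    return dict(sorted(out.items()))
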