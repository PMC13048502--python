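"""Indirect effects: net-effect matrices, collectivity, condition number.

The equilibrium of a community solves ``x* = (I - A*)^{-1} 1``, and the
element ``(I - A*)^{-1}_{ij}`` is the *net* effect of species j on the
equilibrium abundance of species i: the direct interaction plus every chain
of indirect effects, summed by the Neumann series

    (I - A*)^{-1} = I + A* + (A*)^2 + (A*)^3 + ...

The series converges iff the *collectivity* phi — the spectral radius of
A* — is below 1.  Past phi = 1, long indirect chains dominate and the net
effect of a species decouples from its direct interactions; the Pearson
correlation between off-diagonal elements of A* and of (I - A*)^{-1} is the
summary statistic used for that decoupling.

The *condition number* kappa (ratio of largest to smallest singular value,
by default of I - A*, the operator actually inverted) measures how
measurement error on the interaction coefficients is amplified into error on
predicted abundances; the measurement-error experiment below turns that into
a prediction-success probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityState, _offdiag
from .ensembles import ConfigurationError, InteractionMatrix
from .equilibria import (
    DegenerateEquilibriumError,
    is_feasible,
    is_linearly_stable,
    jacobian,
)

__all__ = [
    "CollectivityReport",
    "net_effects",
    "neumann_partial_sum",
    "collectivity_phi",
    "phi_bounds",
    "condition_number",
    "kappa_min_bound",
    "direct_net_correlation",
    "collectivity_report",
    "prediction_error_experiment",
    "assembly_from_pairs_experiment",
]


def net_effects(A_star: np.ndarray) -> np.ndarray:
    """(I - A*)^{-1}; element (i, j) is the net effect of j on i."""
    A_star = np.asarray(A_star, dtype=float)
    n = A_star.shape[0]
    try:
        return np.linalg.inv(np.eye(n) - A_star)
    except np.linalg.LinAlgError as exc:
        raise DegenerateEquilibriumError(str(exc)) from exc


def neumann_partial_sum(A_star: np.ndarray, order: int) -> np.ndarray:
    """Partial sum I + A* + ... + (A*)^order of the net-effect expansion."""
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    A_star = np.asarray(A_star, dtype=float)
    n = A_star.shape[0]
    total = np.eye(n)
    term = np.eye(n)
    for _ in range(order):
        term = term @ A_star
        total = total + term
    return total


def abundance_expansion(A_star: np.ndarray, order: int) -> np.ndarray:
    """Per-species abundance as truncated chains of indirect effects.

    Row sums of the Neumann partial sum: x_i ~ 1 + sum_j A*_ij + sum_jk
    A*_ik A*_kj + ... up to the given order.
    """
    return neumann_partial_sum(A_star, order).sum(axis=1)


def collectivity_phi(A_star: np.ndarray) -> float:
    """Spectral radius of A* (zero-diagonal convention)."""
    A_star = np.asarray(A_star, dtype=float)
    if A_star.size == 0:
        return 0.0
    return float(np.abs(np.linalg.eigvals(A_star)).max())


def phi_bounds(
    S_star: int, mu_star: float, sigma_star: float, reading: str = "sqrt"
) -> float:
    """Random-matrix estimate of the spectral radius of A*.

    For a fully connected matrix with off-diagonal mean mu* and sd sigma*,
    the spectrum is a circular-law bulk of radius ~ sqrt(S*-1)·sigma* plus a
    mean-field outlier at ~ (S*-1)|mu*|; the estimate is the larger of the
    two.  ``reading="printed"`` uses the linear (S*-1)·sigma* noise term
    instead of the circular-law square root.
    """
    if S_star < 2:
        raise ConfigurationError(f"S_star must be >= 2, got {S_star}")
    outlier = (S_star - 1) * abs(mu_star)
    if reading == "sqrt":
        bulk = np.sqrt(S_star - 1.0) * sigma_star
    elif reading == "printed":
        bulk = (S_star - 1.0) * sigma_star
    else:
        raise ConfigurationError(f"unknown phi_bounds reading {reading!r}")
    return float(max(outlier, bulk))


def condition_number(A_star: np.ndarray, target: str = "I_minus_A") -> float:
    """Ratio of largest to smallest singular value of the target matrix.

    ``target="I_minus_A"`` (default) conditions the operator inverted to get
    net effects; ``target="A"`` conditions the raw interaction matrix.  A
    singular target is reported as ``inf`` rather than raised.
    """
    A_star = np.asarray(A_star, dtype=float)
    n = A_star.shape[0]
    if target == "I_minus_A":
        M = np.eye(n) - A_star
    elif target == "A":
        M = A_star
    else:
        raise ConfigurationError(f"unknown condition-number target {target!r}")
    if not np.any(M):
        raise ConfigurationError("target matrix is identically zero")
    s = np.linalg.svd(M, compute_uv=False)
    if s[-1] <= s[0] * max(M.shape) * np.finfo(float).eps:
        return float("inf")  # numerically singular target
    return float(s[0] / s[-1])


def kappa_min_bound(
    S_star: int,
    mu_grid: np.ndarray,
    sigma_grid: np.ndarray,
    pool_size: int = 80,
    n_samples: int = 400,
    seed: int | None = None,
) -> float:
    """Monte-Carlo lower-envelope estimate of kappa(I - A*) for EC communities.

    For each EC-compatible (mu, sigma) on the grid — pairs whose pool is
    expected to contain at least one exclusionary element — random
    S*-subsets of fresh pools are screened for feasibility, stability and
    EC, and the smallest observed condition number is returned.  A
    calibratable stand-in for the closed-form random-matrix bound; by
    construction it is non-exceeding on samples from the same ensemble.
    """
    from .ec_metrics import ec_report, p_exclusionary_element
    from .equilibria import community_from_subset
    from .ensembles import EnsembleSpec, sample_matrix

    if S_star < 3:
        raise ConfigurationError(f"S_star must be >= 3, got {S_star}")
    rng = np.random.default_rng(seed)
    best = np.inf
    for mu in np.asarray(mu_grid, dtype=float):
        for sigma in np.asarray(sigma_grid, dtype=float):
            if sigma <= 0 or p_exclusionary_element(mu, sigma, pool_size) < 0.5:
                continue
            spec = EnsembleSpec(S=pool_size, mu=float(mu), sigma=float(sigma))
            matrix = sample_matrix(spec, seed=int(rng.integers(2**31 - 1)))
            for _ in range(n_samples):
                idx = rng.choice(pool_size, size=S_star, replace=False)
                comm = community_from_subset(matrix, idx)
                if comm is None or not ec_report(comm).is_ec:
                    continue
                best = min(best, condition_number(comm.A_star))
    return float(best)


def direct_net_correlation(A_star: np.ndarray) -> tuple[float, float, float]:
    """Pearson r between direct and net off-diagonal effects, its two-sided
    p-value, and the fraction of positive off-diagonal net effects."""
    A_star = np.asarray(A_star, dtype=float)
    n = A_star.shape[0]
    if n < 3:
        raise ConfigurationError("direct/net correlation requires S* >= 3")
    direct = _offdiag(A_star)
    net = _offdiag(net_effects(A_star))
    frac_pos = float((net > 0).mean())
    if np.allclose(direct, direct[0]) or np.allclose(net, net[0]):
        return float("nan"), float("nan"), frac_pos
    r, p = stats.pearsonr(direct, net)
    return float(r), float(p), frac_pos


@dataclass
class CollectivityReport:
    phi: float
    kappa: float
    pearson_direct_net: float
    p_value: float
    frac_positive_net: float
    neumann_converges: bool


def collectivity_report(
    community: CommunityState, kappa_target: str = "I_minus_A"
) -> CollectivityReport:
    phi = collectivity_phi(community.A_star)
    kappa = condition_number(community.A_star, target=kappa_target)
    if community.S_star >= 3:
        r, p, frac = direct_net_correlation(community.A_star)
    else:  # a pair has too few off-diagonal elements for a correlation
        net = _offdiag(net_effects(community.A_star))
        r, p, frac = float("nan"), float("nan"), float((net > 0).mean())
    return CollectivityReport(
        phi=phi,
        kappa=kappa,
        pearson_direct_net=r,
        p_value=p,
        frac_positive_net=frac,
        neumann_converges=bool(phi < 1.0),
    )


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def _perturbed_offdiag(
    A: np.ndarray, rel_error: float, rng: np.random.Generator, noise: str
) -> np.ndarray:
    """Measurement-noise model: each directed off-diagonal coefficient gets
    independent Gaussian noise; multiplicative noise leaves zeros at zero."""
    n = A.shape[0]
    eps = rng.normal(0.0, rel_error, size=(n, n))
    np.fill_diagonal(eps, 0.0)
    if noise == "multiplicative":
        out = A * (1.0 + eps)
    elif noise == "additive":
        out = A + eps
        np.fill_diagonal(out, 0.0)
    else:
        raise ConfigurationError(f"unknown noise model {noise!r}")
    return out


def coexistence_predicted(A_star: np.ndarray) -> bool:
    """Would a practitioner holding this matrix predict full coexistence?

    Prediction = the full set is feasible and linearly stable under the
    (possibly mismeasured) matrix.
    """
    try:
        feas, x = is_feasible(A_star)
    except DegenerateEquilibriumError:
        return False
    if not feas:
        return False
    return is_linearly_stable(jacobian(A_star, x)).stable


def prediction_error_experiment(
    community_pool: list[CommunityState],
    kappa_target: float,
    rel_error: float = 0.1,
    n_reps: int = 500,
    seed: int | None = None,
    band: float = 0.2,
    noise: str = "multiplicative",
    target: str = "I_minus_A",
) -> tuple[float, int]:
    """Success rate of coexistence predictions under measurement error.

    Communities with condition number within ``band`` (relative) of
    ``kappa_target`` are selected; replicates cycle over them, perturb every
    off-diagonal coefficient with Gaussian noise of relative sd
    ``rel_error``, and score a success when the perturbed matrix still
    predicts coexistence of the full set (the truth, by construction).
    Returns (success fraction, replicates used).
    """
    if rel_error < 0:
        raise ConfigurationError(f"rel_error must be >= 0, got {rel_error}")
    if n_reps < 1:
        raise ConfigurationError(f"n_reps must be >= 1, got {n_reps}")
    lo, hi = kappa_target * (1 - band), kappa_target * (1 + band)
    selected = [
        c
        for c in community_pool
        if c.verified and lo <= condition_number(c.A_star, target=target) <= hi
    ]
    if not selected:
        raise ConfigurationError(
            f"no community with kappa({target}) in [{lo:.3g}, {hi:.3g}]"
        )
    rng = np.random.default_rng(seed)
    successes = 0
    for k in range(n_reps):
        comm = selected[k % len(selected)]
        if rel_error == 0:
            successes += 1
            continue
        A_pert = _perturbed_offdiag(comm.A_star, rel_error, rng, noise)
        if coexistence_predicted(A_pert):
            successes += 1
    return successes / n_reps, n_reps


def assembly_from_pairs_experiment(
    matrix: InteractionMatrix,
    set_size: int,
    n_trials: int,
    seed: int | None = None,
    phi_bin_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble communities from pairwise coexistence and score the outcome.

    Draw random species sets whose every pair coexists in isolation (no
    coefficient below −1 between members), test whether the full set is
    feasible and stable, and tabulate the success rate against the set's
    collectivity phi.  Sets with an excluding pair are ineligible and do not
    count as trials.
    """
    if set_size < 3:
        raise ConfigurationError(f"set_size must be >= 3, got {set_size}")
    if set_size > matrix.S:
        raise ConfigurationError(
            f"set_size {set_size} exceeds pool size {matrix.S}"
        )
    rng = np.random.default_rng(seed)
    if phi_bin_edges is None:
        phi_bin_edges = np.array([0.0, 0.5, 1.0, 1.5, 2.0, np.inf])
    records = []
    for _ in range(n_trials):
        idx = rng.choice(matrix.S, size=set_size, replace=False)
        A_sub = matrix.A[np.ix_(idx, idx)]
        if np.any(np.triu((A_sub < -1.0) | (A_sub.T < -1.0), k=1)):
            continue  # not assemblable from pairwise coexistence
        phi = collectivity_phi(A_sub)
        records.append((phi, coexistence_predicted(A_sub)))
    if not records:
        return pd.DataFrame(
            {"phi_bin": pd.Categorical([]), "n_trials": [], "success_rate": []}
        )
    df = pd.DataFrame(records, columns=["phi", "success"])
    df["phi_bin"] = pd.cut(df["phi"], phi_bin_edges)
    grouped = df.groupby("phi_bin", observed=True).agg(
        n_trials=("success", "size"), success_rate=("success", "mean")
    )
    return grouped.reset_index()
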