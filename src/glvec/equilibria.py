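"""Algebraic equilibria, feasibility, linear stability and subset sampling.

At a GLV equilibrium the surviving species satisfy the linear system
``(I - A*) x* = 1``; a candidate community is *feasible* when the solution is
strictly positive in every component, and *linearly stable* when every
eigenvalue of the Jacobian ``J = diag(r x*) (A* - I)`` has negative real
part.  Because the equilibrium condition is linear and growth rates enter the
Jacobian only as a positive row scaling, both ``x*`` and the stability verdict
are independent of ``r``.

The module also provides the direct subset-sampling route to stable
communities (pick a random subset, test feasibility and stability), the
May-type random-matrix instability threshold for moderate communities, and
the Routh–Hurwitz feedback diagnostic Λ2 = C1·C2 − C3 computed from the
characteristic polynomial of the Jacobian.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .community import CommunityState, _offdiag
from .ensembles import ConfigurationError, InteractionMatrix

__all__ = [
    "DegenerateEquilibriumError",
    "StabilityReport",
    "solve_equilibrium",
    "is_feasible",
    "jacobian",
    "is_linearly_stable",
    "community_from_subset",
    "sample_stable_subsets",
    "enumerate_stable_subsets",
    "may_threshold",
]

STABILITY_TOL = 1e-9


class DegenerateEquilibriumError(np.linalg.LinAlgError):
    """(I - A*) is singular: the candidate equilibrium is degenerate."""


def solve_equilibrium(A_star: np.ndarray) -> np.ndarray:
    """Solve (I - A*) x = 1.  No positivity requirement at this stage."""
    A_star = np.asarray(A_star, dtype=float)
    n = A_star.shape[0]
    M = np.eye(n) - A_star
    try:
        x = np.linalg.solve(M, np.ones(n))
    except np.linalg.LinAlgError as exc:
        raise DegenerateEquilibriumError(str(exc)) from exc
    if not np.all(np.isfinite(x)):
        raise DegenerateEquilibriumError("non-finite equilibrium solution")
    return x


def is_feasible(A_star: np.ndarray) -> tuple[bool, np.ndarray]:
    """True iff every component of the equilibrium is strictly positive."""
    x = solve_equilibrium(A_star)
    return bool(np.all(x > 0)), x


def jacobian(
    A_star: np.ndarray,
    x_star: np.ndarray,
    r_star: np.ndarray | None = None,
    convention: str = "derived",
) -> np.ndarray:
    """Jacobian of the GLV dynamics at an interior equilibrium.

    The derivative of the dynamics gives ``J_ij = r_i x*_i A*_ij`` for i != j
    and ``J_ii = -r_i x*_i`` (``convention="derived"``, the default).  The
    ``"printed"`` convention flips the sign of the off-diagonal part and is
    kept only for comparison.
    """
    A_star = np.asarray(A_star, dtype=float)
    x_star = np.asarray(x_star, dtype=float)
    n = A_star.shape[0]
    if A_star.shape != (n, n) or x_star.shape != (n,):
        raise ValueError("dimension mismatch between A_star and x_star")
    if np.any(x_star <= 0):
        raise ValueError("x_star must be strictly positive")
    if r_star is None:
        r_star = np.ones(n)
    else:
        r_star = np.asarray(r_star, dtype=float)
        if r_star.shape != (n,):
            raise ValueError("dimension mismatch between A_star and r_star")
    sign = 1.0 if convention == "derived" else -1.0
    if convention not in ("derived", "printed"):
        raise ValueError(f"unknown Jacobian convention {convention!r}")
    core = sign * A_star - np.eye(n)
    return (r_star * x_star)[:, None] * core


@dataclass
class StabilityReport:
    """Linear-stability diagnostics for one community Jacobian."""

    eigenvalues: np.ndarray
    stable: bool
    marginal: bool
    max_real_part: float
    char_coeffs: np.ndarray  # C_1 ... C_n of λ^n + C1 λ^{n-1} + ... + Cn
    lambda2: float  # Routh-Hurwitz Λ2 = C1·C2 − C3
    may_mu_c: float | None = None
    violates_may: bool | None = None


def _char_coeffs(eigenvalues: np.ndarray) -> np.ndarray:
    """Monic characteristic-polynomial coefficients from the spectrum.

    Built from the eigenvalues (elementary symmetric polynomials via
    ``numpy.poly``) rather than determinant expansion, which is robust at the
    community sizes considered here (S* <= ~15).
    """
    coeffs = np.poly(eigenvalues)  # [1, C1, ..., Cn]
    return np.real_if_close(coeffs[1:], tol=1e6).astype(float)


def is_linearly_stable(
    J: np.ndarray,
    mu_star: float | None = None,
    sigma_star: float | None = None,
    tol: float = STABILITY_TOL,
    may_reading: str = "sqrt",
) -> StabilityReport:
    """Full stability report: spectrum, Routh-Hurwitz Λ2, May diagnostic.

    A community is accepted as stable only when ``max Re(λ) < -tol``;
    a spectrum with ``|max Re(λ)| <= tol`` is flagged marginal and rejected,
    avoiding neutral directions born of floating-point noise.
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError(f"Jacobian must be square, got shape {J.shape}")
    eig = np.linalg.eigvals(J)
    max_re = float(eig.real.max())
    stable = max_re < -tol
    marginal = abs(max_re) <= tol
    C = _char_coeffs(eig)
    n = C.size
    c1 = C[0] if n >= 1 else 0.0
    c2 = C[1] if n >= 2 else 0.0
    c3 = C[2] if n >= 3 else 0.0
    lam2 = float(c1 * c2 - c3)
    mu_c = violates = None
    if mu_star is not None and sigma_star is not None and n >= 2:
        mu_c = may_threshold(n, sigma_star, reading=may_reading)
        violates = bool(mu_star < mu_c)
    return StabilityReport(
        eigenvalues=eig,
        stable=stable,
        marginal=marginal,
        max_real_part=max_re,
        char_coeffs=C,
        lambda2=lam2,
        may_mu_c=mu_c,
        violates_may=violates,
    )


def may_threshold(S_star: int, sigma_star: float, reading: str = "sqrt") -> float:
    """Random-matrix instability threshold on the mean interaction strength.

    For a large community with off-diagonal statistics (mu*, sigma*), the
    eigenvalue bulk of the rescaled Jacobian destabilizes when mean
    competition is stronger (more negative) than

        mu_c = sqrt(S*/2) * sigma* - 1        (reading="sqrt", default)

    i.e. the community is expected unstable when ``mu* < mu_c``.  The
    threshold rises with diversity and heterogeneity, so moderate-size
    communities that remain stable *below* it (as the sampled EC communities
    routinely do) violate the large-S prediction.  ``reading="printed"``
    gives the literal linear form (S*/2)·sigma* − 1.
    """
    if S_star < 2:
        raise ConfigurationError(f"S_star must be >= 2, got {S_star}")
    if sigma_star < 0:
        raise ConfigurationError(f"sigma_star must be >= 0, got {sigma_star}")
    if reading == "sqrt":
        return float(np.sqrt(S_star / 2.0) * sigma_star - 1.0)
    if reading == "printed":
        return float((S_star / 2.0) * sigma_star - 1.0)
    raise ConfigurationError(f"unknown may_threshold reading {reading!r}")


def community_from_subset(
    matrix: InteractionMatrix,
    indices: np.ndarray,
    origin: str = "sampled",
    tol: float = STABILITY_TOL,
) -> CommunityState | None:
    """Build and verify the community on ``indices``.

    Returns ``None`` when the subset is infeasible, unstable or degenerate.
    """
    idx = np.sort(np.asarray(indices, dtype=int))
    A_sub = matrix.A[np.ix_(idx, idx)]
    try:
        feas, x = is_feasible(A_sub)
    except DegenerateEquilibriumError:
        return None
    if not feas:
        return None
    r_sub = matrix.r[idx]
    rep = is_linearly_stable(jacobian(A_sub, x, r_sub), tol=tol)
    if not rep.stable:
        return None
    return CommunityState(
        pool_indices=idx,
        x_star=x,
        A_star=A_sub,
        r_star=r_sub,
        feasible=True,
        stable=True,
        origin=origin,
    )


def sample_stable_subsets(
    matrix: InteractionMatrix,
    sizes: list[int] | tuple[int, ...],
    n_samples: int,
    seed: int | np.random.Generator | None = None,
    dedup: bool = False,
) -> list[CommunityState]:
    """Uniformly sample species subsets and keep the feasible + stable ones.

    For each requested size, ``n_samples`` subsets are drawn without
    replacement within a draw and with replacement across draws; duplicate
    subsets are allowed unless ``dedup`` is set.
    """
    S = matrix.S
    for size in sizes:
        if size < 1 or size > S:
            raise ConfigurationError(f"subset size {size} outside [1, {S}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accepted: list[CommunityState] = []
    for size in sizes:
        seen: set[tuple[int, ...]] = set()
        for _ in range(n_samples):
            idx = np.sort(rng.choice(S, size=size, replace=False))
            key = tuple(int(i) for i in idx)
            if dedup:
                if key in seen:
                    continue
                seen.add(key)
            comm = community_from_subset(matrix, idx)
            if comm is not None:
                accepted.append(comm)
    return accepted


def enumerate_stable_subsets(
    matrix: InteractionMatrix, max_size: int | None = None
) -> list[CommunityState]:
    """Brute-force oracle: test every subset (intended for S <= 12 pools)."""
    S = matrix.S
    if S > 16:
        raise ConfigurationError("exhaustive enumeration is limited to S <= 16")
    max_size = S if max_size is None else max_size
    out: list[CommunityState] = []
    for size in range(1, max_size + 1):
        for idx in itertools.combinations(range(S), size):
            comm = community_from_subset(matrix, np.array(idx))
            if comm is not None:
                out.append(comm)
    return out
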