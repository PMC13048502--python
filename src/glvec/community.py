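"""Container for a surviving or candidate community.

A :class:`CommunityState` records which species of the pool make up the
community, their equilibrium relative yields ``x*``, the interaction
submatrix ``A*`` among them, and verification flags.  The measured interaction
statistics ``mu_star`` / ``sigma_star`` are always recomputed from ``A*``
(never cached) so they cannot go stale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class StateError(RuntimeError):
    """Operation applied to a community in an inconsistent or unverified state."""


@dataclass
class CommunityState:
    pool_indices: np.ndarray
    x_star: np.ndarray
    A_star: np.ndarray
    r_star: np.ndarray
    feasible: bool
    stable: bool
    origin: str = "sampled"  # "dynamics" or "sampled"

    def __post_init__(self) -> None:
        self.pool_indices = np.sort(np.asarray(self.pool_indices, dtype=int))
        self.x_star = np.asarray(self.x_star, dtype=float)
        self.A_star = np.asarray(self.A_star, dtype=float)
        self.r_star = np.asarray(self.r_star, dtype=float)
        n = self.pool_indices.size
        if self.x_star.shape != (n,):
            raise StateError("x_star length does not match pool_indices")
        if self.A_star.shape != (n, n):
            raise StateError("A_star shape does not match pool_indices")
        if np.any(np.diag(self.A_star) != 0.0):
            raise StateError("A_star diagonal must be exactly zero")
        if np.any(self.x_star <= 0):
            raise StateError("x_star must be strictly positive")

    @property
    def S_star(self) -> int:
        return self.pool_indices.size

    @property
    def mu_star(self) -> float:
        """Mean of the off-diagonal elements of A*, recomputed on access."""
        return float(_offdiag(self.A_star).mean()) if self.S_star > 1 else 0.0

    @property
    def sigma_star(self) -> float:
        """Std (ddof=0) of the off-diagonal elements of A*, recomputed on access."""
        return float(_offdiag(self.A_star).std()) if self.S_star > 1 else 0.0

    @property
    def verified(self) -> bool:
        return self.feasible and self.stable


def _offdiag(A: np.ndarray) -> np.ndarray:
    """Flattened off-diagonal elements of a square matrix."""
    n = A.shape[0]
    return A[~np.eye(n, dtype=bool)]
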