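"""Random and structured interaction-matrix ensembles for the GLV model.

The community model works with rescaled interaction coefficients
``A_ij = a_ij K_j / K_i`` (effect of species *j* on species *i*, expressed
relative to self-regulation) and relative yields ``x_i = N_i / K_i``.  All
ensembles therefore produce a square matrix ``A`` with an exactly zero
diagonal: self-regulation is the explicit ``-x_i`` term of the dynamics and is
never stored in the matrix.

Available structures
--------------------
``random``
    i.i.d. Normal(mu, sigma) off-diagonals, masked by independent
    Bernoulli(connectivity) links (directed Erdős–Rényi by default).
``symmetric``
    A_ij = A_ji exactly; pairs drawn once.
``antisymmetric``
    centered pairs with correlation ``rho`` (default −1):
    A_ij − mu = −(A_ji − mu) on realized links.
``triangular``
    upper triangle (i < j) random, lower triangle zero — a fully nested
    competitive hierarchy in who-affects-whom.
``k_correlated``
    A_ij = a_ij K_j / K_i with a_ij ~ Normal(mu, sigma) and carrying
    capacities K ~ Uniform[k_low, k_high]; rows/columns inherit correlations
    from the K heterogeneity (large-K species impact others most and are
    impacted least).
``crossfeeding``
    single-resource competition with cross-feeding,
    B_ij = C_ij − 2·γ_j/(γ_i + γ_j) − α_ij, with consumption traits γ drawn
    uniformly and sorted in decreasing order (species index order equals the
    competitive hierarchy), weak extra competition α ~ Normal(alpha_mean,
    alpha_sd) and cross-feeding benefits C_ij ~ Uniform[c_low, c_high].

All Normal(m, s) notation uses the standard deviation as second argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "EnsembleSpec",
    "InteractionMatrix",
    "ConfigurationError",
    "GenerationError",
    "MatrixFormatError",
    "STRUCTURES",
    "sample_matrix",
    "sample_growth_rates",
    "sample_carrying_capacities",
    "read_matrix_csv",
    "write_matrix_csv",
]

STRUCTURES = (
    "random",
    "symmetric",
    "antisymmetric",
    "triangular",
    "k_correlated",
    "crossfeeding",
)


class ConfigurationError(ValueError):
    """Invalid ensemble or protocol configuration."""


class GenerationError(RuntimeError):
    """A sampled quantity came out non-finite."""


class MatrixFormatError(ValueError):
    """A user-supplied interaction matrix violates the format contract."""


@dataclass(frozen=True)
class EnsembleSpec:
    """Full parameterization of an interaction-matrix ensemble.

    Parameters mirror the statistical model of the study: off-diagonal
    interaction strengths with mean ``mu`` and standard deviation ``sigma``
    (both dimensionless, relative to self-regulation), link probability
    ``connectivity``, growth-rate heterogeneity ``sigma_r`` around a mean of
    1, and the auxiliary distributions of the structured variants.
    """

    S: int
    mu: float = -0.5
    sigma: float = 0.25
    connectivity: float = 1.0
    structure: str = "random"
    sigma_r: float = 0.0
    k_low: float = 0.5
    k_high: float = 1.5
    gamma_low: float = 0.3
    gamma_high: float = 0.7
    alpha_mean: float = 0.1
    alpha_sd: float = 0.01
    c_low: float = 0.0
    c_high: float = 1.0
    paired_mask: bool = False
    antisym_rho: float = -1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ConfigurationError(f"pool size S must be >= 2, got {self.S}")
        if self.sigma < 0:
            raise ConfigurationError(f"sigma must be >= 0, got {self.sigma}")
        if not 0.0 <= self.connectivity <= 1.0:
            raise ConfigurationError(
                f"connectivity must lie in [0, 1], got {self.connectivity}"
            )
        if self.structure not in STRUCTURES:
            raise ConfigurationError(
                f"unknown structure {self.structure!r}; expected one of {STRUCTURES}"
            )
        if self.sigma_r < 0:
            raise ConfigurationError(f"sigma_r must be >= 0, got {self.sigma_r}")
        if self.k_low <= 0:
            raise ConfigurationError(f"k_low must be > 0, got {self.k_low}")
        if self.gamma_low <= 0:
            raise ConfigurationError(f"gamma_low must be > 0, got {self.gamma_low}")
        for lo, hi, name in (
            (self.k_low, self.k_high, "k"),
            (self.gamma_low, self.gamma_high, "gamma"),
            (self.c_low, self.c_high, "c"),
        ):
            if lo > hi:
                raise ConfigurationError(f"{name}_low={lo} exceeds {name}_high={hi}")
        if self.alpha_sd < 0:
            raise ConfigurationError(f"alpha_sd must be >= 0, got {self.alpha_sd}")
        if not -1.0 <= self.antisym_rho <= 1.0:
            raise ConfigurationError(
                f"antisym_rho must lie in [-1, 1], got {self.antisym_rho}"
            )

    def with_seed(self, seed: int | None) -> "EnsembleSpec":
        return replace(self, seed=seed)


@dataclass
class InteractionMatrix:
    """A pool's rescaled interaction coefficients plus demographic vectors.

    ``A[i, j]`` is the effect of species ``j`` on species ``i``.  The diagonal
    is exactly zero; ``r`` and ``K`` are strictly positive.
    """

    A: np.ndarray
    r: np.ndarray
    K: np.ndarray
    spec: EnsembleSpec | None = None
    seed_used: int | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise MatrixFormatError(f"A must be square, got shape {self.A.shape}")
        if not np.all(np.isfinite(self.A)):
            raise GenerationError("non-finite entries in interaction matrix")
        if np.any(np.diag(self.A) != 0.0):
            raise MatrixFormatError("diagonal of A must be exactly zero")
        self.r = np.asarray(self.r, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        if self.r.shape != (self.S,) or self.K.shape != (self.S,):
            raise MatrixFormatError("r and K must be length-S vectors")
        if np.any(self.r <= 0) or np.any(self.K <= 0):
            raise MatrixFormatError("r and K must be strictly positive")

    @property
    def S(self) -> int:
        return self.A.shape[0]


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) draws with non-positive values rejected and redrawn.

    Rejection keeps the seeded stream deterministic and slightly truncates
    the distribution (negligible for sd << mean).
    """
    out = rng.normal(mean, sd, size=n)
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise GenerationError("could not draw strictly positive values")


def sample_growth_rates(
    S: int, sigma_r: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Intrinsic growth rates ~ Normal(1, sigma_r), strictly positive."""
    if sigma_r < 0:
        raise ConfigurationError(f"sigma_r must be >= 0, got {sigma_r}")
    if sigma_r == 0:
        return np.ones(S)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return _positive_normal(rng, 1.0, sigma_r, S)


def sample_carrying_capacities(
    S: int,
    k_low: float = 0.5,
    k_high: float = 1.5,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Carrying capacities ~ Uniform[k_low, k_high] with k_low > 0."""
    if k_low <= 0:
        raise ConfigurationError(f"k_low must be > 0, got {k_low}")
    if k_low > k_high:
        raise ConfigurationError(f"k_low={k_low} exceeds k_high={k_high}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.uniform(k_low, k_high, size=S)


def _connectivity_mask(
    rng: np.random.Generator, S: int, C: float, paired: bool
) -> np.ndarray:
    """Boolean off-diagonal link mask. Directed by default; ``paired`` makes
    the link realized (or not) for both directions of a pair together."""
    if C >= 1.0:
        mask = np.ones((S, S), dtype=bool)
    elif paired:
        upper = rng.random((S, S)) < C
        mask = np.triu(upper, k=1)
        mask = mask | mask.T
    else:
        mask = rng.random((S, S)) < C
    np.fill_diagonal(mask, False)
    return mask


def sample_matrix(spec: EnsembleSpec, seed: int | None = None) -> InteractionMatrix:
    """Draw one interaction matrix (plus r and K) from the ensemble.

    Deterministic given ``seed`` (falling back to ``spec.seed``).
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    S = spec.S
    mu, sigma = spec.mu, spec.sigma

    K = np.ones(S)
    if spec.structure == "random":
        A = rng.normal(mu, sigma, size=(S, S))
    elif spec.structure == "symmetric":
        draw = rng.normal(mu, sigma, size=(S, S))
        upper = np.triu(draw, k=1)
        A = upper + upper.T
    elif spec.structure == "antisymmetric":
        rho = spec.antisym_rho
        d1 = rng.normal(0.0, 1.0, size=(S, S))
        d2 = rng.normal(0.0, 1.0, size=(S, S))
        upper = np.triu(np.ones((S, S), dtype=bool), k=1)
        A = np.full((S, S), mu)
        A[upper] += sigma * d1[upper]
        lower_dev = rho * d1 + np.sqrt(max(0.0, 1.0 - rho**2)) * d2
        A.T[upper] += sigma * lower_dev[upper]
    elif spec.structure == "triangular":
        A = np.triu(rng.normal(mu, sigma, size=(S, S)), k=1)
    elif spec.structure == "k_correlated":
        a = rng.normal(mu, sigma, size=(S, S))
        K = sample_carrying_capacities(S, spec.k_low, spec.k_high, rng)
        A = a * K[None, :] / K[:, None]
    elif spec.structure == "crossfeeding":
        gamma = np.sort(rng.uniform(spec.gamma_low, spec.gamma_high, size=S))[::-1]
        alpha = rng.normal(spec.alpha_mean, spec.alpha_sd, size=(S, S))
        cross = rng.uniform(spec.c_low, spec.c_high, size=(S, S))
        A = cross - 2.0 * gamma[None, :] / (gamma[:, None] + gamma[None, :]) - alpha
    else:  # pragma: no cover - guarded by EnsembleSpec
        raise ConfigurationError(f"unknown structure {spec.structure!r}")

    paired = spec.paired_mask or spec.structure in ("symmetric", "antisymmetric")
    mask = _connectivity_mask(rng, S, spec.connectivity, paired)
    A = np.where(mask, A, 0.0)
    np.fill_diagonal(A, 0.0)
    if not np.all(np.isfinite(A)):
        raise GenerationError("sampled matrix contains non-finite values")

    r = sample_growth_rates(S, spec.sigma_r, rng)
    return InteractionMatrix(A=A, r=r, K=K, spec=spec, seed_used=seed)


# ---------------------------------------------------------------------------
# CSV interface for user-supplied matrices
# ---------------------------------------------------------------------------

def write_matrix_csv(path: str | Path, A: np.ndarray, labels: list[str] | None = None) -> None:
    """Write a square matrix as decimal text with 17 significant digits."""
    A = np.asarray(A, dtype=float)
    lines = []
    if labels is not None:
        if len(labels) != A.shape[0]:
            raise MatrixFormatError("label count does not match matrix size")
        lines.append(",".join(labels))
    for row in A:
        lines.append(",".join(format(v, ".17g") for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a square interaction matrix (optional single header row).

    The diagonal must be exactly zero; violations raise
    :class:`MatrixFormatError` with row/column diagnostics.
    """
    raw = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not raw:
        raise MatrixFormatError(f"{path}: empty file")
    labels: list[str] | None = None
    first = raw[0].split(",")

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    if not all(_is_number(tok) for tok in first):
        labels = [tok.strip() for tok in first]
        raw = raw[1:]
    rows = []
    for i, ln in enumerate(raw):
        toks = ln.split(",")
        vals = []
        for j, tok in enumerate(toks):
            try:
                vals.append(float(tok))
            except ValueError:
                raise MatrixFormatError(
                    f"{path}: non-numeric entry at row {i}, column {j}: {tok!r}"
                ) from None
        rows.append(vals)
    n = len(rows)
    if any(len(row) != n for row in rows):
        widths = sorted({len(row) for row in rows})
        raise MatrixFormatError(
            f"{path}: matrix is not square ({n} rows, column counts {widths})"
        )
    A = np.array(rows, dtype=float)
    bad = np.nonzero(np.diag(A) != 0.0)[0]
    if bad.size:
        raise MatrixFormatError(
            f"{path}: diagonal must be exactly zero (nonzero at indices {bad.tolist()})"
        )
    return A, labels
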