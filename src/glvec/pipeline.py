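"""Experiment drivers: phase diagram, fraction/collectivity/intransitivity
scans and the single-matrix analysis entry point.

Each driver is a thin loop over the library: it spawns per-cell random
streams from one master seed (so cells are independent and reorderable),
runs the relevant sampler or integrator, and returns a tidy table that the
CLI and the analysis scripts write as CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import CommunityState
from .collectivity import collectivity_report
from .dynamics import (
    DEFAULT_T1,
    DEFAULT_T2,
    DIVERGENCE_CAP,
    EXTINCTION_THRESHOLD,
    STATIONARITY_TOL,
    run_replicates,
)
from .ec_metrics import ec_report, regime_boundaries
from .ensembles import ConfigurationError, EnsembleSpec, read_matrix_csv, sample_matrix
from .equilibria import (
    is_feasible,
    is_linearly_stable,
    jacobian,
    sample_stable_subsets,
)
from .intransitivity import intransitivity_report

log = logging.getLogger("glvec")

__all__ = ["RunConfig", "run_phase_diagram", "run_scan", "analyze_matrix",
           "community_table", "write_run_manifest"]


@dataclass
class RunConfig:
    """Configuration for the experiment drivers.

    Defaults follow the study conditions: pools of S = 80 species, 100
    systems per (mu, sigma) cell on a 26 x 21 grid over mu in (-2, 0.5) and
    sigma in (0, 1), integration windows t1 = 3000 and t2 = 100, and
    sizes 3..12 for the subset sampler.
    """

    experiment: str = "phase_diagram"
    mu_min: float = -2.0
    mu_max: float = 0.5
    n_mu: int = 26
    sigma_min: float = 0.0
    sigma_max: float = 1.0
    n_sigma: int = 21
    S: int = 80
    n_systems: int = 100
    subset_budget: int = 100_000
    sizes: tuple[int, ...] = tuple(range(3, 13))
    t1: float = DEFAULT_T1
    t2: float = DEFAULT_T2
    extinction_threshold: float = EXTINCTION_THRESHOLD
    divergence_cap: float = DIVERGENCE_CAP
    stationarity_tol: float = STATIONARITY_TOL
    structure: str = "random"
    connectivity: float = 1.0
    sigma_r: float = 0.0
    crossing_level: float = 0.5
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.n_mu < 2 or self.n_sigma < 2:
            raise ConfigurationError("grid resolutions must be >= 2")

    def mu_grid(self) -> np.ndarray:
        return np.linspace(self.mu_min, self.mu_max, self.n_mu)

    def sigma_grid(self) -> np.ndarray:
        # sigma = 0 exactly is a degenerate ensemble; keep the grid interior
        grid = np.linspace(self.sigma_min, self.sigma_max, self.n_sigma)
        return grid[grid > 0]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "sizes" in data:
            data["sizes"] = tuple(data["sizes"])
        return cls(**data)


def _cell_seed(master: int, i: int, j: int) -> int:
    """Counter-based per-cell seed so cells are independent and reorderable."""
    return int(
        np.random.SeedSequence([master, i, j]).generate_state(1, np.uint32)[0]
        % (2**31 - 1)
    )


def run_phase_diagram(config: RunConfig) -> pd.DataFrame:
    """Per-(mu, sigma) cell: integrate n_systems pools, tally EC prevalence.

    ``ec_fraction`` divides EC states by stationary states with >= 3
    coexisting species (NaN where the denominator is zero).
    """
    rows = []
    for i, mu in enumerate(config.mu_grid()):
        for j, sigma in enumerate(config.sigma_grid()):
            spec = EnsembleSpec(
                S=config.S,
                mu=float(mu),
                sigma=float(sigma),
                structure=config.structure,
                connectivity=config.connectivity,
                sigma_r=config.sigma_r,
            )
            seed = _cell_seed(config.seed, i, j)
            _, tally = run_replicates(
                spec,
                config.n_systems,
                seed=seed,
                t1=config.t1,
                t2=config.t2,
                extinction_threshold=config.extinction_threshold,
                divergence_cap=config.divergence_cap,
                stationarity_tol=config.stationarity_tol,
            )
            n3 = tally["stationary_3plus"]
            rows.append(
                {
                    "mu": mu,
                    "sigma": sigma,
                    "n_systems": config.n_systems,
                    "n_stationary_3plus": n3,
                    "n_ec": tally["ec_states"],
                    "ec_fraction": tally["ec_states"] / n3 if n3 else np.nan,
                    "n_diverged": tally["diverged"],
                    "n_nonstationary": tally["non_stationary"],
                    "seed": seed,
                }
            )
            log.info(
                "phase-diagram cell mu=%.3f sigma=%.3f seed=%d ec=%d of %d",
                mu, sigma, seed, tally["ec_states"], n3,
            )
    return pd.DataFrame(rows)


def boundary_table(config: RunConfig) -> pd.DataFrame:
    bounds = regime_boundaries(
        config.S, config.mu_grid(), crossing_level=config.crossing_level,
        sigma_max=config.sigma_max,
    )
    return pd.DataFrame(
        {"mu": bounds.mu_grid, "sigma1c": bounds.sigma1c, "sigma2c": bounds.sigma2c}
    )


def community_table(communities: list[CommunityState], seed: int) -> pd.DataFrame:
    """One row per accepted community with EC and collectivity metrics."""
    rows = []
    for c in communities:
        ec = ec_report(c)
        rep = is_linearly_stable(jacobian(c.A_star, c.x_star, c.r_star))
        col = collectivity_report(c)
        from .collectivity import condition_number

        rows.append(
            {
                "S_star": c.S_star,
                "mu_star": c.mu_star,
                "sigma_star": c.sigma_star,
                "is_ec": ec.is_ec,
                "fraction_excluding": ec.fraction_excluding,
                "phi": col.phi,
                "kappa": col.kappa,
                "kappa_A": condition_number(c.A_star, target="A"),
                "pearson_direct_net": col.pearson_direct_net,
                "p_value": col.p_value,
                "frac_positive_net": col.frac_positive_net,
                "lambda2": rep.lambda2,
                "origin": c.origin,
                "seed": seed,
                "subset": ";".join(str(int(i)) for i in c.pool_indices),
            }
        )
    return pd.DataFrame(rows)


def sample_grid_communities(
    config: RunConfig,
    per_cell_samples: int | None = None,
    mu_values: np.ndarray | None = None,
    sigma_values: np.ndarray | None = None,
) -> list[tuple[CommunityState, float, float]]:
    """Subset-sample stable communities over the (mu, sigma) grid.

    Returns (community, mu, sigma) triples; the per-cell budget splits the
    total subset budget evenly over cells and sizes.
    """
    mu_values = config.mu_grid() if mu_values is None else mu_values
    sigma_values = config.sigma_grid() if sigma_values is None else sigma_values
    n_cells = len(mu_values) * len(sigma_values)
    per_cell = per_cell_samples or max(
        1, config.subset_budget // (n_cells * len(config.sizes))
    )
    out = []
    for i, mu in enumerate(mu_values):
        for j, sigma in enumerate(sigma_values):
            seed = _cell_seed(config.seed, i, j)
            spec = EnsembleSpec(
                S=config.S,
                mu=float(mu),
                sigma=float(sigma),
                structure=config.structure,
                connectivity=config.connectivity,
            )
            matrix = sample_matrix(spec, seed=seed)
            comms = sample_stable_subsets(
                matrix, list(config.sizes), per_cell, seed=seed
            )
            out.extend((c, float(mu), float(sigma)) for c in comms)
    return out


def run_scan(config: RunConfig, kind: str) -> pd.DataFrame:
    """Sample stable communities across the grid and apply a metrics module.

    kind="fraction": EC fractions per community (Fig-2C-style table);
    kind="collectivity": phi/kappa/correlation table;
    kind="intransitivity": LRE/RPS summary per structure and size.
    """
    if kind == "intransitivity":
        from .intransitivity import intransitivity_scan

        return intransitivity_scan(
            S=config.S,
            mu=-0.75,
            sigma=0.5,
            structures=[config.structure] if config.structure != "random"
            else ["random", "reshuffled"],
            sizes=list(config.sizes),
            n_communities=max(1, config.n_systems),
            seed=config.seed,
        )
    if kind not in ("fraction", "collectivity"):
        raise ConfigurationError(f"unknown scan kind {kind!r}")
    triples = sample_grid_communities(config)
    comms = [c for c, _, _ in triples]
    table = community_table(comms, config.seed)
    if table.empty:
        log.warning("scan %s found no stable communities", kind)
        return table
    table["mu_pool"] = [mu for _, mu, _ in triples]
    table["sigma_pool"] = [s for _, _, s in triples]
    if kind == "fraction":
        cols = [
            "mu_pool", "sigma_pool", "S_star", "mu_star", "sigma_star",
            "is_ec", "fraction_excluding", "origin", "seed", "subset",
        ]
        return table[cols]
    return table


def analyze_matrix(
    path: str | Path, r: np.ndarray | None = None
) -> dict:
    """Treat a user-supplied CSV matrix as A*: verify and report everything."""
    A, labels = read_matrix_csv(path)
    n = A.shape[0]
    feas, x = is_feasible(A)
    result: dict = {
        "S_star": int(n),
        "labels": labels,
        "feasible": bool(feas),
    }
    if not feas:
        result["stable"] = False
        return result
    r_vec = np.ones(n) if r is None else np.asarray(r, dtype=float)
    rep = is_linearly_stable(jacobian(A, x, r_vec))
    result["stable"] = bool(rep.stable)
    result["x_star"] = [float(v) for v in x]
    result["lambda2"] = rep.lambda2
    if not rep.stable:
        return result
    comm = CommunityState(
        pool_indices=np.arange(n),
        x_star=x,
        A_star=A,
        r_star=r_vec,
        feasible=True,
        stable=True,
        origin="sampled",
    )
    ec = ec_report(comm)
    col = collectivity_report(comm)
    result.update(
        {
            "is_ec": ec.is_ec,
            "n_excluding_pairs": ec.n_excluding_pairs,
            "fraction_excluding": ec.fraction_excluding,
            "phi": col.phi,
            "kappa_I_minus_A": col.kappa,
            "pearson_direct_net": col.pearson_direct_net,
            "p_value": col.p_value,
            "frac_positive_net": col.frac_positive_net,
            "neumann_converges": col.neumann_converges,
        }
    )
    if n >= 3:
        rep_i = intransitivity_report(comm)
        result["rps_fraction"] = rep_i.rps_fraction
        result["lre_fraction_raw"] = rep_i.lre_fraction_raw
        result["n_exclusions"] = rep_i.n_exclusions
    return result


def write_run_manifest(config: RunConfig, out_dir: str | Path, counts: dict) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "counts": counts,
    }
    path = out / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
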