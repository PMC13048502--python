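"""Integrate GLV trajectories and extract the surviving community.

The simulation protocol: start a pool of S species at random initial relative
yields x_i(0) ~ Uniform[0, 1], integrate

    dx_i/dt = r_i x_i (1 - x_i + sum_{j != i} A_ij x_j)

for a duration ``t1`` (default 3000 time units, with time rescaled so r = 1
sets the unit), hard-zero any species whose relative yield falls below the
extinction threshold, then integrate a further stationarity window ``t2``
(default 100) and accept the endpoint as stationary only if no surviving
abundance moved by more than the stationarity tolerance across the window.
Runs whose abundances exceed the divergence cap (the unbounded mutualistic
outgrowth regime) are flagged diverged and never contribute communities.

Integration uses scipy's adaptive explicit Runge-Kutta (RK45).  Because the
solver cannot modify its own state mid-run, extinction is applied between
integration segments: the run is split into segments of at most
``segment_length`` time units and species below threshold at a segment
boundary are zeroed (abundance and dynamics) for the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .community import CommunityState, StateError
from .ensembles import ConfigurationError, EnsembleSpec, InteractionMatrix, sample_matrix
from . import equilibria

__all__ = [
    "Trajectory",
    "IntegrationError",
    "integrate_glv",
    "surviving_community",
    "run_replicates",
    "DEFAULT_T1",
    "DEFAULT_T2",
    "EXTINCTION_THRESHOLD",
    "DIVERGENCE_CAP",
    "STATIONARITY_TOL",
]

DEFAULT_T1 = 3000.0
DEFAULT_T2 = 100.0
EXTINCTION_THRESHOLD = 1e-6
DIVERGENCE_CAP = 1e6
STATIONARITY_TOL = 1e-3


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message carries time and state diagnostics."""


@dataclass
class Trajectory:
    """Checkpointed GLV trajectory (rows of ``abundances`` = time points)."""

    times: np.ndarray
    abundances: np.ndarray
    status: str  # "stationary" | "non_stationary" | "diverged"
    extinction_threshold: float = EXTINCTION_THRESHOLD

    @property
    def final(self) -> np.ndarray:
        return self.abundances[-1]

    def to_csv(self, path) -> None:
        """Dump checkpoints as CSV (time, x_0 ... x_{S-1}) for debugging."""
        import pandas as pd

        S = self.abundances.shape[1]
        frame = pd.DataFrame(self.abundances, columns=[f"x_{i}" for i in range(S)])
        frame.insert(0, "time", self.times)
        frame.to_csv(path, index=False)


def _glv_rhs(r: np.ndarray, A: np.ndarray, alive: np.ndarray):
    ra = r * alive

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        xa = np.maximum(x, 0.0) * alive
        return ra * xa * (1.0 - xa + A @ xa)

    return rhs


def integrate_glv(
    matrix: InteractionMatrix,
    x0: np.ndarray,
    t1: float = DEFAULT_T1,
    t2: float = DEFAULT_T2,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
    divergence_cap: float = DIVERGENCE_CAP,
    stationarity_tol: float = STATIONARITY_TOL,
    segment_length: float = 100.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the pool dynamics and classify the outcome."""
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial abundances must be non-negative")
    if t1 <= 0 or t2 <= 0:
        raise ValueError("t1 and t2 must be positive")
    if not 0 < extinction_threshold < 1 < divergence_cap:
        raise ValueError("require 0 < extinction_threshold < 1 < divergence_cap")

    A, r = matrix.A, matrix.r
    alive = (x0 >= extinction_threshold).astype(float)
    x = x0 * alive

    def diverged_event(t: float, y: np.ndarray) -> float:
        return divergence_cap - float(np.max(y))

    diverged_event.terminal = True
    diverged_event.direction = -1

    times = [0.0]
    states = [x.copy()]
    t_now = 0.0
    checkpoints: list[float] = []
    t = 0.0
    while t < t1 - 1e-9:
        t_next = min(t + segment_length, t1)
        checkpoints.append(t_next)
        t = t_next
    checkpoints.append(t1 + t2)

    x_at_t1: np.ndarray | None = None
    status = "non_stationary"
    for t_next in checkpoints:
        sol = solve_ivp(
            _glv_rhs(r, A, alive),
            (t_now, t_next),
            x,
            method="RK45",
            rtol=rtol,
            atol=atol,
            events=diverged_event,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failure at t={sol.t[-1]:.3f}, |x|={np.linalg.norm(sol.y[:, -1]):.3e}: "
                f"{sol.message}"
            )
        x = np.maximum(sol.y[:, -1], 0.0) * alive
        t_now = float(sol.t[-1])
        if sol.status == 1 or np.max(x) > divergence_cap:
            times.append(t_now)
            states.append(x.copy())
            return Trajectory(
                np.array(times), np.array(states), "diverged", extinction_threshold
            )
        # hard-zero extinct species for the remainder of the run
        newly_dead = (x < extinction_threshold) & (alive > 0)
        if newly_dead.any():
            alive = alive * (~newly_dead)
            x = x * alive
        times.append(t_now)
        states.append(x.copy())
        if abs(t_now - t1) < 1e-9:
            x_at_t1 = x.copy()

    if x_at_t1 is None:  # t1 checkpoint coincides with start of final window
        x_at_t1 = states[-2]
    x_end = states[-1]
    denom = np.maximum(x_at_t1, extinction_threshold)
    rel_change = np.abs(x_end - x_at_t1) / denom
    if float(rel_change.max(initial=0.0)) < stationarity_tol:
        status = "stationary"
    return Trajectory(np.array(times), np.array(states), status, extinction_threshold)


def surviving_community(
    trajectory: Trajectory, matrix: InteractionMatrix
) -> CommunityState:
    """Extract survivors of a stationary trajectory as a verified community.

    Feasibility and stability are re-checked algebraically; the stored
    ``x_star`` is the endpoint of the dynamics.
    """
    if trajectory.status != "stationary":
        raise StateError(
            f"cannot extract survivors from a {trajectory.status} trajectory"
        )
    final = trajectory.final
    idx = np.nonzero(final >= trajectory.extinction_threshold)[0]
    if idx.size == 0:
        raise StateError("no species survived above the extinction threshold")
    A_sub = matrix.A[np.ix_(idx, idx)]
    x_dyn = final[idx]
    feas, _ = equilibria.is_feasible(A_sub)
    rep = equilibria.is_linearly_stable(
        equilibria.jacobian(A_sub, x_dyn, matrix.r[idx])
    )
    return CommunityState(
        pool_indices=idx,
        x_star=x_dyn,
        A_star=A_sub,
        r_star=matrix.r[idx],
        feasible=feas,
        stable=rep.stable,
        origin="dynamics",
    )


def run_replicates(
    spec: EnsembleSpec,
    n_systems: int,
    seed: int | None = None,
    t1: float = DEFAULT_T1,
    t2: float = DEFAULT_T2,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
    divergence_cap: float = DIVERGENCE_CAP,
    stationarity_tol: float = STATIONARITY_TOL,
    **integrate_kwargs,
) -> tuple[list[CommunityState], dict[str, int]]:
    """Simulate ``n_systems`` independent pools, each with a fresh matrix and
    fresh x0 ~ Uniform[0, 1]^S, and tally the outcomes.

    The tally counts ``stationary_3plus`` (stationary states with >= 3
    coexisting species), ``ec_states`` (those containing at least one
    excluding pair), ``diverged`` and ``non_stationary`` runs.  Deterministic
    given ``seed``.
    """
    from .ec_metrics import ec_report  # local import to avoid a cycle

    if n_systems < 1:
        raise ConfigurationError(f"n_systems must be >= 1, got {n_systems}")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(n_systems)
    communities: list[CommunityState] = []
    tally = {
        "n_systems": n_systems,
        "stationary": 0,
        "stationary_3plus": 0,
        "ec_states": 0,
        "diverged": 0,
        "non_stationary": 0,
    }
    for child in streams:
        rng = np.random.default_rng(child)
        mat_seed = int(rng.integers(0, 2**31 - 1))
        matrix = sample_matrix(spec, seed=mat_seed)
        x0 = rng.uniform(0.0, 1.0, size=spec.S)
        traj = integrate_glv(
            matrix,
            x0,
            t1=t1,
            t2=t2,
            extinction_threshold=extinction_threshold,
            divergence_cap=divergence_cap,
            stationarity_tol=stationarity_tol,
            **integrate_kwargs,
        )
        if traj.status == "diverged":
            tally["diverged"] += 1
            continue
        if traj.status == "non_stationary":
            tally["non_stationary"] += 1
            continue
        tally["stationary"] += 1
        try:
            comm = surviving_community(traj, matrix)
        except StateError:
            tally["non_stationary"] += 1
            tally["stationary"] -= 1
            continue
        communities.append(comm)
        if comm.S_star >= 3:
            tally["stationary_3plus"] += 1
            if comm.verified and ec_report(comm).is_ec:
                tally["ec_states"] += 1
    return communities, tally
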