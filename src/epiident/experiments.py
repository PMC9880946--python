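"""Numerical experiments: indistinguishable trajectory pairs and the
(tau, n) distance surface.

A "master" parameter set generates a daily-new-cases vector; candidate
(tau, n) pairs are scored by the Euclidean distance between their daily
cases and the master's, scaled by the population size.  The low-distance
valley in the (n, tau) plane is hyperbola-like and is tracked by the two
analytic observation curves, which is the geometric face of practical
unidentifiability: many clearly distinct parameter pairs produce nearly
the same epidemic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from epiident.epidemic_models import (
    EpidemicParams,
    IntegrationError,
    ModelSpec,
    Trajectory,
    integrate,
)

__all__ = [
    "DistanceSurface",
    "trajectory_distance",
    "distance_surface",
    "twin_trajectories",
    "twin_parameter_sets",
]


@dataclass(frozen=True)
class DistanceSurface:
    """Trajectory-distance matrix over a (n, tau) grid.

    ``D[i, j]`` is the distance at ``(n_grid[i], tau_grid[j])``; failed
    integrations are NaN.  ``minima`` lists strict 8-neighbour local
    minima as (i, j) index pairs.
    """

    model_id: str
    n_grid: np.ndarray
    tau_grid: np.ndarray
    D: np.ndarray
    master: EpidemicParams
    minima: tuple[tuple[int, int], ...]

    def column_argmin(self) -> np.ndarray:
        """Index of the minimising tau for each n-column (NaN-aware)."""
        out = np.empty(self.n_grid.size, dtype=int)
        for i in range(self.n_grid.size):
            col = self.D[i]
            out[i] = int(np.nanargmin(col))
        return out


def trajectory_distance(master: Trajectory, candidate: Trajectory) -> float:
    """Euclidean norm of the difference of daily-new-cases vectors, scaled
    by the population size N.  Both trajectories must share the same
    integer-day grid."""
    if master.day_bins.size != candidate.day_bins.size or not np.allclose(
        master.day_bins, candidate.day_bins
    ):
        raise ValueError(
            "trajectories are on different day grids "
            f"({master.day_bins.size - 1} vs {candidate.day_bins.size - 1} bins)"
        )
    diff = master.daily_new_cases - candidate.daily_new_cases
    return float(np.linalg.norm(diff) / master.params.N)


def distance_surface(
    model_spec: ModelSpec,
    master_params: EpidemicParams,
    n_range: tuple[float, float] = (2.2, 12.0),
    tau_range: tuple[float, float] = (0.02, 1.2),
    grid_shape: tuple[int, int] = (60, 60),
    horizon: float = 300.0,
    I0: float = 1.0,
) -> DistanceSurface:
    """Evaluate the daily-cases distance to the master run over a (n, tau) grid.

    The default horizon of 300 days with day-scale recovery rates lets the
    epidemic run essentially to completion, so the tail contributes
    negligibly to the distance.  Grid points where integration fails are
    recorded as NaN rather than aborting the sweep.
    """
    n_grid = np.linspace(*n_range, grid_shape[0])
    tau_grid = np.linspace(*tau_range, grid_shape[1])
    master = integrate(model_spec, master_params, t_end=horizon, I0=I0)
    D = np.full(grid_shape, np.nan)
    for i, n in enumerate(n_grid):
        for j, tau in enumerate(tau_grid):
            params = replace(master_params, tau=float(tau), n=float(n))
            try:
                cand = integrate(model_spec, params, t_end=horizon, I0=I0)
                D[i, j] = trajectory_distance(master, cand)
            except (IntegrationError, ValueError):
                continue
    return DistanceSurface(
        model_id=model_spec.model_id,
        n_grid=n_grid,
        tau_grid=tau_grid,
        D=D,
        master=master_params,
        minima=tuple(_local_minima(D)),
    )


def _local_minima(D: np.ndarray) -> list[tuple[int, int]]:
    """Strict 8-neighbour local minima of D, ignoring NaN cells."""
    minima = []
    rows, cols = D.shape
    for i in range(rows):
        for j in range(cols):
            v = D[i, j]
            if not math.isfinite(v):
                continue
            neighbours = [
                D[a, b]
                for a in range(max(i - 1, 0), min(i + 2, rows))
                for b in range(max(j - 1, 0), min(j + 2, cols))
                if (a, b) != (i, j) and math.isfinite(D[a, b])
            ]
            if neighbours and all(v < w for w in neighbours):
                minima.append((i, j))
    return minima


def twin_parameter_sets(gamma: float = 1.0 / 7.0, N: float = 10_000.0) -> list[EpidemicParams]:
    """Baseline (n=6, tau=gamma*R0/((n-1)-R0) with R0=2.5) and two alternate
    (n, tau) pairs that produce near-indistinguishable pairwise epidemics."""
    pairs = [(6.0, gamma * 2.5 / (5.0 - 2.5)), (8.46, 0.09), (2.454, 1.091)]
    return [EpidemicParams(tau=tau, gamma=gamma, n=n, N=N) for n, tau in pairs]


def twin_trajectories(
    params_list: list[EpidemicParams] | None = None,
    model_spec: ModelSpec = ModelSpec("pairwise_binomial"),
    N: float = 10_000.0,
    I0: float = 1.0,
    horizon: float = 300.0,
) -> tuple[list[Trajectory], np.ndarray]:
    """Integrate a list of parameter sets on a common horizon and return the
    trajectories together with their mutual distance matrix.

    With the default parameter list the first entry is the master run and
    the remaining entries are alternates whose prevalence and daily-new-case
    curves are nearly indistinguishable from it despite clearly different
    (n, tau)."""
    if params_list is None:
        params_list = twin_parameter_sets(N=N)
    trajectories = [
        integrate(model_spec, p, t_end=horizon, I0=I0) for p in params_list
    ]
    k = len(trajectories)
    dist = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            dist[a, b] = dist[b, a] = trajectory_distance(
                trajectories[a], trajectories[b]
            )
    return trajectories, dist
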