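"""Mean-field SIR models on networks: right-hand sides and integration.

Three deterministic descriptions of an SIR epidemic on a contact network
with mean degree ``n`` are provided, all parameterised by the per-link
transmission rate ``tau`` (1/day), the recovery rate ``gamma`` (1/day)
and the population size ``N``:

``sir``
    The classic compartmental model with force of infection tau*n*I*S/N,
    i.e. random mixing with contact rate tau*n.
``pairwise_binomial`` / ``pairwise_poisson``
    The pair-approximation model tracking node counts [S], [I] and pair
    counts [SS], [SI] (pairs counted in both directions), closed at the
    triple level via [ASB] = kappa*[AS][SB]/[S] with kappa = (n-1)/n
    (exact for binomial degree distributions in the large-network limit)
    or kappa = 1 (exact for Poisson).
``ebcm``
    The edge-based compartmental model: a single ODE for theta, the
    probability that a random neighbour of an initially susceptible test
    node has not yet transmitted to it, with S(t) = N*psi(theta(t)) and
    psi the degree-distribution PGF (Poisson built in,
    psi(x) = exp(n(x-1))).

All time units are days.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MODEL_IDS",
    "EpidemicParams",
    "ModelSpec",
    "InitialCondition",
    "Trajectory",
    "DegenerateStateError",
    "IntegrationError",
    "rhs_sir",
    "rhs_pairwise",
    "rhs_ebcm",
    "default_initial_condition",
    "integrate",
]

MODEL_IDS = ("sir", "pairwise_binomial", "pairwise_poisson", "ebcm")


class DegenerateStateError(ValueError):
    """Raised when a closure becomes undefined, e.g. [S] = 0 in the pairwise model."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the solver diagnostics."""


@dataclass(frozen=True)
class EpidemicParams:
    """Parameter vector mu = (tau, gamma, n, N) shared by all models.

    Parameters
    ----------
    tau : float
        Per-link transmission rate (1/day).
    gamma : float
        Recovery rate (1/day); 1/gamma is the mean infectious period.
    n : float
        Mean degree of the contact network (dimensionless).
    N : float
        Population size (number of nodes).
    """

    tau: float
    gamma: float
    n: float
    N: float = 10_000.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if not self.n > 0:
            raise ValueError(f"mean degree n must be positive, got {self.n}")
        if not self.N >= 1:
            raise ValueError(f"population size N must be >= 1, got {self.N}")

    def to_dict(self) -> dict:
        return {"tau": self.tau, "gamma": self.gamma, "n": self.n, "N": self.N}


@dataclass(frozen=True)
class ModelSpec:
    """Identifies one of the four mean-field models and its structural constants.

    ``eigen_slope(n)`` is the linear function l(n) appearing in the leading
    eigenvalue lambda = tau*l(n) - gamma of the disease-free steady state:
    l(n) = n for sir, n-2 for the binomial-closure pairwise model, and
    n-1 for the Poisson-closure pairwise model and the EBCM.
    """

    model_id: str

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(
                f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}"
            )

    # -- structural constants -------------------------------------------------

    @property
    def is_pairwise(self) -> bool:
        return self.model_id in ("pairwise_binomial", "pairwise_poisson")

    def kappa(self, n: float) -> float:
        """Triple-closure constant: (n-1)/n for binomial, 1 for Poisson."""
        if self.model_id == "pairwise_binomial":
            return (n - 1.0) / n
        if self.model_id == "pairwise_poisson":
            return 1.0
        raise ValueError(f"kappa is not defined for model {self.model_id!r}")

    def eigen_slope(self, n: float) -> float:
        """l(n) in lambda = tau*l(n) - gamma."""
        if self.model_id == "sir":
            return n
        if self.model_id == "pairwise_binomial":
            return n - 2.0
        return n - 1.0  # pairwise_poisson and ebcm

    @property
    def eigen_slope_offset(self) -> float:
        """c such that l(n) = n - c; also the singularity of 1/l(n)."""
        return {"sir": 0.0, "pairwise_binomial": 2.0,
                "pairwise_poisson": 1.0, "ebcm": 1.0}[self.model_id]

    def psi(self, theta: float | np.ndarray, n: float):
        """Poisson degree-distribution PGF, psi(x) = exp(n(x-1)) (ebcm only)."""
        if self.model_id != "ebcm":
            raise ValueError("psi is only attached to the ebcm model")
        return np.exp(n * (np.asarray(theta, dtype=float) - 1.0))


SIR = ModelSpec("sir")
PAIRWISE_BINOMIAL = ModelSpec("pairwise_binomial")
PAIRWISE_POISSON = ModelSpec("pairwise_poisson")
EBCM = ModelSpec("ebcm")


@dataclass(frozen=True)
class InitialCondition:
    """Initial state for one of the models.

    Exactly the fields relevant to ``model_id`` are set:

    * sir: ``S0``, ``I0`` (individuals);
    * pairwise: ``S0``, ``I0`` (node counts) and ``SS0``, ``SI0`` (pair
      counts, pairs counted in both directions);
    * ebcm: ``theta0``, ``phi_S0``, ``phi_R0`` (probabilities).
    """

    model_id: str
    S0: float | None = None
    I0: float | None = None
    SS0: float | None = None
    SI0: float | None = None
    theta0: float | None = None
    phi_S0: float | None = None
    phi_R0: float | None = None

    def __post_init__(self) -> None:
        if self.model_id == "sir" or self.model_id in (
            "pairwise_binomial",
            "pairwise_poisson",
        ):
            if self.S0 is None or self.I0 is None:
                raise ValueError("S0 and I0 are required")
            if self.S0 < 0 or self.I0 < 0:
                raise ValueError("node counts must be nonnegative")
            if self.model_id != "sir":
                if self.SS0 is None or self.SI0 is None:
                    raise ValueError("pairwise models require SS0 and SI0")
                if self.SS0 < 0 or self.SI0 < 0:
                    raise ValueError("pair counts must be nonnegative")
        elif self.model_id == "ebcm":
            if self.theta0 is None or self.phi_S0 is None or self.phi_R0 is None:
                raise ValueError("ebcm requires theta0, phi_S0 and phi_R0")
            if not (0.0 < self.theta0 <= 1.0):
                raise ValueError("theta0 must lie in (0, 1]")
            if self.phi_S0 < 0 or self.phi_R0 < 0:
                raise ValueError("phi_S0 and phi_R0 must be nonnegative")
            if self.phi_S0 + self.phi_R0 > self.theta0 + 1e-12:
                raise ValueError("phi_S0 + phi_R0 must not exceed theta0")
        else:
            raise ValueError(f"unknown model_id {self.model_id!r}")

    def state_vector(self) -> np.ndarray:
        if self.model_id == "sir":
            return np.array([self.S0, self.I0], dtype=float)
        if self.model_id in ("pairwise_binomial", "pairwise_poisson"):
            return np.array([self.S0, self.I0, self.SS0, self.SI0], dtype=float)
        return np.array([self.theta0], dtype=float)


@dataclass
class Trajectory:
    """Time-gridded solution of one model with epidemiological summaries.

    Attributes
    ----------
    times : ndarray
        Output grid (days), strictly increasing.
    states : ndarray, shape (len(times), dim)
        Raw model state at each output time.
    prevalence : ndarray
        I(t), number currently infected (individuals).
    cumulative_incidence : ndarray
        C(t), cumulative number ever infected beyond the initial seeding.
    day_bins : ndarray
        Integer days bounding the daily-new-case bins.
    daily_new_cases : ndarray
        First differences of C over consecutive integer days
        (individuals/day); ``len(daily_new_cases) == len(day_bins) - 1``.
    """

    model_spec: ModelSpec
    params: EpidemicParams
    times: np.ndarray
    states: np.ndarray
    prevalence: np.ndarray
    cumulative_incidence: np.ndarray
    day_bins: np.ndarray
    daily_new_cases: np.ndarray
    state_names: tuple[str, ...] = ()

    def final_susceptible_fraction(self) -> float:
        """S(t_end)/N; for the EBCM, psi(theta(t_end))."""
        if self.model_spec.model_id == "ebcm":
            return float(
                self.model_spec.psi(self.states[-1, 0], self.params.n)
            )
        return float(self.states[-1, 0] / self.params.N)

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times}
        for j, name in enumerate(self.state_names):
            data[name] = self.states[:, j]
        data["prevalence"] = self.prevalence
        data["cumulative_incidence"] = self.cumulative_incidence
        frame = pd.DataFrame(data)
        daily = np.full(len(self.times), np.nan)
        # place each day's new cases at the right edge of its bin when on-grid
        lookup = {float(d): v for d, v in zip(self.day_bins[1:], self.daily_new_cases)}
        for i, t in enumerate(self.times):
            if float(t) in lookup:
                daily[i] = lookup[float(t)]
        frame["daily_new_cases"] = daily
        return frame

    def to_csv(self, path: str | Path) -> None:
        """Write the trajectory as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {"model_id": self.model_spec.model_id, "params": self.params.to_dict()}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2)
        )


# -- right-hand sides ----------------------------------------------------------


def rhs_sir(state: Sequence[float], params: EpidemicParams) -> tuple[float, float]:
    """Classic SIR vector field: dS/dt = -tau*n*I*S/N, dI/dt = tau*n*I*S/N - gamma*I."""
    S, I = state
    foi = params.tau * params.n * I * S / params.N
    return (-foi, foi - params.gamma * I)


def rhs_pairwise(
    state: Sequence[float],
    params: EpidemicParams,
    kappa_variant: str = "binomial",
) -> tuple[float, float, float, float]:
    """Pairwise SIR vector field for ([S], [I], [SS], [SI]).

    The triple closure [ASB] = kappa*[AS][SB]/[S] is applied with
    kappa = (n-1)/n (``kappa_variant='binomial'``) or kappa = 1
    (``'poisson'``).  Pairs are counted in both directions, so the
    disease-free state is ([S],[I],[SS],[SI]) = (N, 0, nN, 0).

    Raises
    ------
    DegenerateStateError
        If [S] = 0, where the closure is undefined.
    """
    S, I, SS, SI = state
    if S <= 0.0:
        raise DegenerateStateError(
            f"pairwise closure undefined at [S] = {S}; requires [S] > 0"
        )
    if kappa_variant == "binomial":
        kappa = (params.n - 1.0) / params.n
    elif kappa_variant == "poisson":
        kappa = 1.0
    else:
        raise ValueError(f"unknown kappa_variant {kappa_variant!r}")
    tau, gamma = params.tau, params.gamma
    dS = -tau * SI
    dI = tau * SI - gamma * I
    dSI = -(tau + gamma) * SI + tau * kappa * SI * (SS - SI) / S
    dSS = -2.0 * tau * kappa * SS * SI / S
    return (dS, dI, dSS, dSI)


def rhs_ebcm(
    theta: float, params: EpidemicParams, init: InitialCondition
) -> float:
    """EBCM vector field for theta with the Poisson PGF.

    dtheta/dt = -tau*theta + tau*phi_S(0)*exp(n(theta-1))
                + gamma*(1-theta) + tau*phi_R(0)
    """
    tau, gamma, n = params.tau, params.gamma, params.n
    return (
        -tau * theta
        + tau * init.phi_S0 * math.exp(n * (theta - 1.0))
        + gamma * (1.0 - theta)
        + tau * init.phi_R0
    )


def default_initial_condition(
    model_spec: ModelSpec, params: EpidemicParams, I0: float = 1.0
) -> InitialCondition:
    """Initial state with ``I0`` infected individuals placed uniformly at random.

    For the pairwise models the pair counts follow the mean-field
    random-placement convention [SI](0) = n*I0*(N-I0)/N and
    [SS](0) = n*(N-I0)^2/N, consistent with [SS] = nN at the disease-free
    state.  For the EBCM the disease-free state theta = 1 is perturbed by
    setting phi_S(0) = 1 - I0/N.
    """
    N = params.N
    if not (0.0 < I0 < N):
        raise ValueError(f"I0 must lie strictly between 0 and N={N}, got {I0}")
    if model_spec.model_id == "sir":
        return InitialCondition("sir", S0=N - I0, I0=I0)
    if model_spec.is_pairwise:
        S0 = N - I0
        return InitialCondition(
            model_spec.model_id,
            S0=S0,
            I0=I0,
            SS0=params.n * S0 * S0 / N,
            SI0=params.n * I0 * S0 / N,
        )
    return InitialCondition(
        "ebcm", theta0=1.0, phi_S0=1.0 - I0 / N, phi_R0=0.0
    )


# -- integration ---------------------------------------------------------------

_STATE_NAMES = {
    "sir": ("S", "I"),
    "pairwise_binomial": ("S", "I", "SS", "SI"),
    "pairwise_poisson": ("S", "I", "SS", "SI"),
    "ebcm": ("theta", "R"),
}


def _augmented_rhs(
    model_spec: ModelSpec, params: EpidemicParams, init: InitialCondition
) -> Callable[[float, np.ndarray], np.ndarray]:
    """RHS including cumulative incidence (or R for the EBCM) bookkeeping."""
    mid = model_spec.model_id
    if mid == "sir":

        def rhs(t, y):
            dS, dI = rhs_sir(y[:2], params)
            return np.array([dS, dI, -dS])  # Cdot = force of infection

        return rhs
    if model_spec.is_pairwise:
        variant = "binomial" if mid == "pairwise_binomial" else "poisson"
        floor = 1e-12 * params.N

        def rhs(t, y):
            # adaptive trial steps can undershoot [S] = 0 or push pair
            # counts slightly negative in burnt-out epidemics; evaluate the
            # closure at the nearest admissible state to keep it stable
            state = np.array(y[:4], dtype=float)
            state[0] = max(state[0], floor)
            state[2] = max(state[2], 0.0)
            state[3] = max(state[3], 0.0)
            dS, dI, dSS, dSI = rhs_pairwise(state, params, variant)
            return np.array([dS, dI, dSS, dSI, params.tau * state[3]])

        return rhs

    def rhs(t, y):  # ebcm: y = (theta, R)
        theta, R = y
        dtheta = rhs_ebcm(theta, params, init)
        S = params.N * model_spec.psi(theta, params.n)
        I = max(params.N - S - R, 0.0)
        return np.array([dtheta, params.gamma * I])

    return rhs


def _prevalence_of(
    model_spec: ModelSpec, params: EpidemicParams, y: np.ndarray
) -> np.ndarray:
    """Prevalence I(t) from the augmented state (works on vectors)."""
    if model_spec.model_id == "ebcm":
        S = params.N * model_spec.psi(y[0], params.n)
        return np.maximum(params.N - S - y[1], 0.0)
    return np.asarray(y[1], dtype=float)


def integrate(
    model_spec: ModelSpec,
    params: EpidemicParams,
    init: InitialCondition | None = None,
    t_end: float | None = None,
    dt_out: float = 1.0,
    rtol: float = 1e-8,
    I0: float = 1.0,
) -> Trajectory:
    """Integrate a model and return its trajectory with daily summaries.

    Uses an adaptive Runge-Kutta scheme (DOP853) with rtol 1e-8 and
    abs tol 1e-10*N, tight enough that final sizes extracted from
    trajectories agree with the implicit final-size equations to ~1e-4.
    If ``t_end`` is omitted, integration stops once prevalence drops
    below 1e-8*N (the epidemic is over) or at t = 500/gamma, whichever
    comes first.

    Parameters
    ----------
    init : InitialCondition, optional
        Defaults to `default_initial_condition` with ``I0`` infected.
    dt_out : float
        Output sampling step (days); daily new cases are always binned
        on integer days regardless of ``dt_out``.
    """
    if init is None:
        init = default_initial_condition(model_spec, params, I0=I0)
    if init.model_id != model_spec.model_id:
        raise ValueError(
            f"initial condition for {init.model_id!r} used with {model_spec.model_id!r}"
        )
    if t_end is not None and not t_end > 0:
        raise ValueError("t_end must be positive")

    N = params.N
    y0 = init.state_vector()
    if model_spec.model_id == "ebcm":
        y0 = np.array([init.theta0, 0.0])
        atol = np.array([1e-14, 1e-10 * N])
    else:
        y0 = np.append(y0, 0.0)  # cumulative incidence starts at 0
        atol = 1e-10 * N

    t_max = t_end if t_end is not None else 500.0 / params.gamma
    events = None
    if t_end is None:

        def quiescent(t, y):
            return float(_prevalence_of(model_spec, params, y) - 1e-8 * N)

        quiescent.terminal = True
        quiescent.direction = -1
        events = [quiescent]

    n_days = int(math.floor(t_max))
    t_eval = np.unique(
        np.concatenate(
            [np.arange(0.0, t_max + 0.5 * dt_out, dt_out), np.arange(0.0, n_days + 1.0)]
        )
    )
    t_eval = t_eval[t_eval <= t_max]

    rhs = _augmented_rhs(model_spec, params, init)
    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        y0,
        method="DOP853",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        events=events,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(
            f"solver failed for {model_spec.model_id}: {sol.message}"
        )

    times = sol.t
    ys = sol.y
    # append the terminal event point so the trajectory really ends at quiescence
    if events is not None and sol.status == 1 and sol.t_events[0].size:
        te = float(sol.t_events[0][0])
        if te > times[-1] + 1e-12:
            times = np.append(times, te)
            ys = np.column_stack([ys, sol.y_events[0][0]])

    prevalence = _prevalence_of(model_spec, params, ys)
    if model_spec.model_id == "ebcm":
        states = ys.T
        cumulative = N * (1.0 - model_spec.psi(ys[0], params.n))
    else:
        states = ys[:-1].T
        cumulative = ys[-1]

    day_bins = np.arange(0.0, math.floor(times[-1]) + 1.0)
    c_days = np.interp(day_bins, times, cumulative)
    daily = np.diff(c_days)

    return Trajectory(
        model_spec=model_spec,
        params=params,
        times=times,
        states=states,
        prevalence=np.asarray(prevalence, dtype=float),
        cumulative_incidence=np.asarray(cumulative, dtype=float),
        day_bins=day_bins,
        daily_new_cases=daily,
        state_names=_STATE_NAMES[model_spec.model_id],
    )
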