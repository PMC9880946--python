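"""The (n, tau) inverse problem: observation curves, intersection, and the
reduced scalar equation f(n) = f(n*).

Given a measured growth rate ``lam`` and final susceptible fraction
``s_inf`` (with the recovery rate ``gamma`` assumed known), each model
defines two curves in the (n, tau) plane:

* the eigenvalue curve  tau = (lam + gamma) / l(n);
* the final-size curve  tau = A(n) * gamma, from the model's implicit
  final-size equation.

Their intersection (n*, tau*) is the point estimate.  Eliminating tau
reduces the system to a single scalar equation:

* pairwise (kappa=(n-1)/n):  lam + gamma = gamma * f(n) with
  f(n) = (s^(1/n) - s^(2/n)) / (s^(2/n) - s) * (n - 2),
  which increases from f_2 = 2(s - sqrt(s))/(s ln s) at n -> 2 to
  f_inf = ln(s)/(s - 1) as n -> infinity (for s above a small threshold);
* EBCM / kappa=1:  lam + gamma = gamma * q * f(n) with
  f(n) = (n - 1)/(n - q) and q = ln(s)/(s - 1) > 1, which decreases
  to 1 as n -> infinity.

Because f is nearly constant, the epsilon-band solution set
{n : |f(n) - f(n*)| < eps} blows up to a half-line of infinite measure for
epsilon comparable to the (tiny) range of f: tau and n are practically
unidentifiable even though the noiseless system has a unique solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from epiident.epidemic_models import EpidemicParams, ModelSpec
from epiident.characteristics import ObservedSummaries

__all__ = [
    "IdentifiabilityCurve",
    "IntersectionResult",
    "FReductionSummary",
    "MonotonicityScan",
    "EpsilonSolutionSet",
    "TauGammaSolution",
    "NoIntersectionError",
    "StructurallyUnidentifiableError",
    "SingularSystemError",
    "tau_from_eigenvalue",
    "tau_from_final_size",
    "default_n_grid",
    "build_curves",
    "intersect_curves",
    "f_pairwise",
    "f_limits_pairwise",
    "f_ebcm",
    "q_of",
    "f_reduction_summary",
    "scan_monotonicity",
    "epsilon_solution_set",
    "solve_tau_gamma_given_n",
]


class NoIntersectionError(RuntimeError):
    """The two observation curves have no common point on the grid: the
    measurement is inconsistent with the model.  Carries the minimal gap."""

    def __init__(self, message: str, min_gap: float):
        super().__init__(message)
        self.min_gap = min_gap


class StructurallyUnidentifiableError(RuntimeError):
    """The two curves coincide identically (SIR): the observation pins down
    only the product tau*n, and every point of the curve is a solution."""


class SingularSystemError(RuntimeError):
    """The 2x2 linear system for (tau, gamma) at fixed n is singular."""


@dataclass(frozen=True)
class IdentifiabilityCurve:
    """One tau(n) observation curve on a stated n-grid."""

    model_id: str
    curve_kind: str  # "eigenvalue" or "final_size"
    n: np.ndarray
    tau: np.ndarray
    observation: ObservedSummaries
    gamma: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.n.tolist(), self.tau.tolist()))


@dataclass(frozen=True)
class IntersectionResult:
    """Crossing of the eigenvalue and final-size curves."""

    n_star: float
    tau_star: float
    gap: float  # max over the grid of |tau_eig - tau_fs|
    all_roots: tuple[float, ...] = ()
    multiple: bool = False


@dataclass(frozen=True)
class MonotonicityScan:
    """Outcome of the numerical monotonicity scan of the pairwise f."""

    s_grid: np.ndarray
    increasing: np.ndarray  # bool per s
    monotone_threshold: float  # largest s at which a decrease was detected (empirical a-bar)


@dataclass(frozen=True)
class FReductionSummary:
    """Closed-form summary of the reduced function f for one model."""

    model_id: str
    s_inf: float
    f2: float | None  # n->2 limit (pairwise only)
    f_inf: float  # n->infinity limit
    q: float | None  # ln(s)/(s-1) (ebcm/kappa=1 only)
    range_width: float


@dataclass(frozen=True)
class EpsilonSolutionSet:
    """The set {n : |f(n) - f(n*)| < epsilon} as a union of intervals.

    ``measure`` is the Lebesgue measure of the set; it is ``math.inf``
    (and ``infinite`` is True) whenever the band reaches the upper end of
    the domain, which happens as soon as epsilon exceeds the distance
    from f(n*) to the bounded limit of f.
    """

    epsilon: float
    n_star: float
    intervals: tuple[tuple[float, float], ...]
    measure: float
    infinite: bool


@dataclass(frozen=True)
class TauGammaSolution:
    tau: float
    gamma: float
    determinant: float

    def __iter__(self):
        return iter((self.tau, self.gamma))


# -- the two tau(n) curves -----------------------------------------------------


def tau_from_eigenvalue(
    n: float | np.ndarray, lam: float, gamma: float, model_spec: ModelSpec
) -> float | np.ndarray:
    """Invert lambda = tau*l(n) - gamma for tau: tau = (lam + gamma)/l(n)."""
    if lam + gamma <= 0:
        raise ValueError(f"lam + gamma must be positive, got {lam + gamma}")
    n = np.asarray(n, dtype=float)
    slope = n - model_spec.eigen_slope_offset
    if np.any(slope <= 0):
        raise ValueError(
            f"n must exceed {model_spec.eigen_slope_offset} for model "
            f"{model_spec.model_id!r}"
        )
    out = (lam + gamma) / slope
    return float(out) if out.ndim == 0 else out


def tau_from_final_size(
    n: float | np.ndarray,
    s_inf: float,
    gamma: float,
    model_spec: ModelSpec,
    phi_S0: float = 1.0,
) -> float | np.ndarray:
    """The tau making the model's final susceptible fraction exactly s_inf.

    sir:        tau = -gamma*ln(s) / (n*(1-s))   (only tau*n is pinned down)
    pairwise:   tau = gamma*(s^(1/n) - s^(2/n)) / (s^(2/n) - s)
    ebcm/k=1:   tau = gamma*ln(s) / (n*phi_S0*s - ln(s) - n)
    """
    if not (0.0 < s_inf < 1.0):
        raise ValueError(f"s_inf must lie in (0, 1) for inversion, got {s_inf}")
    n = np.asarray(n, dtype=float)
    ls = math.log(s_inf)
    mid = model_spec.model_id
    if mid == "sir":
        out = -gamma * ls / (n * (1.0 - s_inf))
    elif mid == "pairwise_binomial":
        if np.any(n <= 2.0):
            raise ValueError("pairwise final-size inversion requires n > 2")
        # expm1 forms avoid the n->2 and s->1 cancellations
        num = -np.exp(ls / n) * np.expm1(ls / n)  # s^(1/n) - s^(2/n)
        den = s_inf * np.expm1((2.0 / n - 1.0) * ls)  # s^(2/n) - s
        out = gamma * num / den
    else:  # pairwise_poisson / ebcm
        den = n * phi_S0 * s_inf - ls - n
        if np.any(den >= 0):
            raise ValueError(
                "final-size inversion undefined: requires n*phi_S0*s - ln s - n < 0 "
                "(n above q = ln(s)/(s-1) when phi_S0 = 1)"
            )
        out = gamma * ls / den
    return float(out) if out.ndim == 0 else out


def default_n_grid(
    model_spec: ModelSpec,
    s_inf: float | None = None,
    n_min: float | None = None,
    n_max: float = 1e3,
    n_points: int = 400,
) -> np.ndarray:
    """Logarithmic n-grid just above the model's domain edge.

    The edge is 2 for the binomial-closure pairwise model, max(1, q) for
    the EBCM/kappa=1 models (q = ln(s)/(s-1)) and 0 for sir.  f flattens
    at large n, so log spacing resolves the knee near the edge.
    """
    if n_min is None:
        edge = model_spec.eigen_slope_offset
        if model_spec.model_id in ("ebcm", "pairwise_poisson") and s_inf is not None:
            edge = max(edge, q_of(s_inf))
        n_min = edge + 1e-3 if edge > 0 else 1e-2
    return np.geomspace(n_min, n_max, n_points)


def build_curves(
    model_spec: ModelSpec,
    observation: ObservedSummaries,
    gamma: float,
    n_grid: np.ndarray | None = None,
) -> tuple[IdentifiabilityCurve, IdentifiabilityCurve]:
    """Evaluate the eigenvalue and final-size curves on a shared n-grid."""
    if n_grid is None:
        n_grid = default_n_grid(model_spec, s_inf=observation.s_inf)
    n_grid = np.asarray(n_grid, dtype=float)
    if n_grid.size == 0:
        raise ValueError("empty n-grid")
    tau_eig = tau_from_eigenvalue(n_grid, observation.lam, gamma, model_spec)
    tau_fs = tau_from_final_size(n_grid, observation.s_inf, gamma, model_spec)
    kw = dict(model_id=model_spec.model_id, observation=observation, gamma=gamma)
    return (
        IdentifiabilityCurve(curve_kind="eigenvalue", n=n_grid, tau=np.asarray(tau_eig), **kw),
        IdentifiabilityCurve(curve_kind="final_size", n=n_grid, tau=np.asarray(tau_fs), **kw),
    )


def intersect_curves(
    curves: tuple[IdentifiabilityCurve, IdentifiabilityCurve],
    structural_rtol: float = 1e-9,
) -> IntersectionResult:
    """Locate (n*, tau*) where the two curves cross.

    Bracketing root-finding on the sign change of tau_eig(n) - tau_fs(n),
    tol 1e-12 in n.  Raises `StructurallyUnidentifiableError` when the
    curves coincide to roundoff (the SIR case) and `NoIntersectionError`
    when the difference never changes sign (inconsistent measurement).
    """
    ceig, cfs = curves
    if ceig.curve_kind != "eigenvalue":
        ceig, cfs = cfs, ceig
    spec = ModelSpec(ceig.model_id)
    obs, gamma = ceig.observation, ceig.gamma
    diff = ceig.tau - cfs.tau
    scale = np.maximum(np.abs(ceig.tau), np.abs(cfs.tau))
    gap = float(np.max(np.abs(diff)))
    if gap <= structural_rtol * float(np.max(scale)):
        raise StructurallyUnidentifiableError(
            "the eigenvalue and final-size curves coincide to roundoff: only a "
            "combination of tau and n is determined (structural unidentifiability)"
        )

    def g(n: float) -> float:
        return tau_from_eigenvalue(n, obs.lam, gamma, spec) - tau_from_final_size(
            n, obs.s_inf, gamma, spec
        )

    sign = np.sign(diff)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    exact = np.nonzero(sign == 0)[0]
    roots = [float(ceig.n[i]) for i in exact]
    for i in idx:
        roots.append(float(brentq(g, ceig.n[i], ceig.n[i + 1], xtol=1e-12, rtol=8.9e-16)))
    if not roots:
        raise NoIntersectionError(
            "curves do not intersect on the grid: the measured (lam, s_inf) pair "
            f"is inconsistent with the model (minimal gap {np.min(np.abs(diff)):.3e})",
            min_gap=float(np.min(np.abs(diff))),
        )
    roots = sorted(roots)
    n_star = roots[0]
    return IntersectionResult(
        n_star=n_star,
        tau_star=float(tau_from_eigenvalue(n_star, obs.lam, gamma, spec)),
        gap=gap,
        all_roots=tuple(roots),
        multiple=len(roots) > 1,
    )


# -- the reduced function f ----------------------------------------------------


def f_pairwise(n: float | np.ndarray, s_inf: float) -> float | np.ndarray:
    """Reduced function of the binomial-closure pairwise model,
    f(n) = (s^(1/n) - s^(2/n)) / (s^(2/n) - s) * (n - 2), for n > 2.

    Satisfies lam + gamma = gamma*f(n) along consistent observations, so
    f nearly constant means (n, tau) nearly unidentifiable.
    """
    if not (0.0 < s_inf < 1.0):
        raise ValueError(f"s_inf must lie in (0, 1), got {s_inf}")
    n = np.asarray(n, dtype=float)
    if np.any(n <= 2.0):
        raise ValueError("f_pairwise requires n > 2")
    ls = math.log(s_inf)
    num = -np.exp(ls / n) * np.expm1(ls / n)
    den = s_inf * np.expm1((2.0 / n - 1.0) * ls)
    out = num / den * (n - 2.0)
    return float(out) if out.ndim == 0 else out


def f_limits_pairwise(s_inf: float) -> tuple[float, float]:
    """Closed-form limits of the pairwise f: (f_2, f_inf) with
    f_2 = 2(s - sqrt(s))/(s ln s) and f_inf = ln(s)/(s - 1).

    Both tend to 1 as s -> 1 (L'Hospital); the removable singularity is
    handled by the closed forms, not numerically.
    """
    if not (0.0 < s_inf <= 1.0):
        raise ValueError(f"s_inf must lie in (0, 1], got {s_inf}")
    if s_inf == 1.0:
        return 1.0, 1.0
    f2 = 2.0 * (s_inf - math.sqrt(s_inf)) / (s_inf * math.log(s_inf))
    f_inf = math.log(s_inf) / (s_inf - 1.0)
    return f2, f_inf


def q_of(s_inf: float) -> float:
    """q = ln(s)/(s - 1) > 1 for s in (0, 1); q(1) = 1 by continuity."""
    if not (0.0 < s_inf <= 1.0):
        raise ValueError(f"s_inf must lie in (0, 1], got {s_inf}")
    if s_inf == 1.0:
        return 1.0
    return math.log(s_inf) / (s_inf - 1.0)


def f_ebcm(n: float | np.ndarray, s_inf: float) -> float | np.ndarray:
    """Reduced function of the EBCM/kappa=1 models, f(n) = (n-1)/(n-q)
    with q = ln(s)/(s-1), for n > q.

    Satisfies lam + gamma = gamma*q*f(n); f decreases to 1 as n -> infinity.
    """
    q = q_of(s_inf)
    n = np.asarray(n, dtype=float)
    if np.any(n <= q):
        raise ValueError(f"f_ebcm requires n > q = {q:.6g}")
    out = (n - 1.0) / (n - q)
    return float(out) if out.ndim == 0 else out


def f_reduction_summary(model_spec: ModelSpec, s_inf: float) -> FReductionSummary:
    """Closed-form limits and range width of f for one model."""
    mid = model_spec.model_id
    if mid == "pairwise_binomial":
        f2, f_inf = f_limits_pairwise(s_inf)
        return FReductionSummary(
            model_id=mid, s_inf=s_inf, f2=f2, f_inf=f_inf, q=None,
            range_width=f_inf - f2,
        )
    if mid in ("ebcm", "pairwise_poisson"):
        q = q_of(s_inf)
        # f decreases from +infinity at n -> q+ to 1; on the conventional
        # reporting window n > 10 the sup deviation from the limit 1 is at n=10
        return FReductionSummary(
            model_id=mid, s_inf=s_inf, f2=None, f_inf=1.0, q=q,
            range_width=float(f_ebcm(10.0, s_inf)) - 1.0,
        )
    raise ValueError(f"no reduced function for model {mid!r}")


def scan_monotonicity(
    s_inf_grid: np.ndarray | None = None,
    n_grid: np.ndarray | None = None,
) -> MonotonicityScan:
    """Numerically scan monotonicity of the pairwise f over s_inf.

    For each s in the grid, tests strict increase of f_pairwise on the
    n-grid.  The empirical monotonicity threshold (the a-bar above which
    f is increasing) is reported as the largest s at which any decrease
    is detected; 0.0 if none is.
    """
    if s_inf_grid is None:
        s_inf_grid = np.arange(0.015, 0.99, 0.005)
    if n_grid is None:
        n_grid = np.geomspace(2.0 + 1e-6, 1e3, 2000)
    s_inf_grid = np.asarray(s_inf_grid, dtype=float)
    increasing = np.empty(s_inf_grid.size, dtype=bool)
    for i, s in enumerate(s_inf_grid):
        vals = f_pairwise(n_grid, float(s))
        increasing[i] = bool(np.all(np.diff(vals) > 0))
    failures = s_inf_grid[~increasing]
    threshold = float(failures.max()) if failures.size else 0.0
    return MonotonicityScan(
        s_grid=s_inf_grid, increasing=increasing, monotone_threshold=threshold
    )


# -- epsilon-band solution set -------------------------------------------------


def _invert_f_pairwise(y: float, s_inf: float, n_hint: float) -> float:
    """Solve f_pairwise(n) = y for n in (2, inf), f strictly increasing."""
    lo = 2.0 + 1e-12
    hi = max(4.0, 2.0 * n_hint)
    g = lambda n: f_pairwise(n, s_inf) - y
    while g(hi) < 0 and hi < 1e15:
        hi *= 10.0
    return float(brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16))


def epsilon_solution_set(
    model_spec: ModelSpec, s_inf: float, n_star: float, epsilon: float
) -> EpsilonSolutionSet:
    """The set {n : |f(n) - f(n*)| < epsilon} and its Lebesgue measure.

    Because f is bounded (pairwise: range (f_2, f_inf); EBCM: limit 1 at
    infinity), the band reaches the upper end of the domain — and the set
    becomes a half-line of infinite measure — as soon as epsilon exceeds
    the gap between f(n*) and the bounded limit.  This is the formal
    statement of practical unidentifiability.
    """
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    mid = model_spec.model_id
    if mid == "pairwise_binomial":
        f2, f_inf = f_limits_pairwise(s_inf)
        f_star = float(f_pairwise(n_star, s_inf))
        y_lo, y_hi = f_star - epsilon, f_star + epsilon
        lo = 2.0 if y_lo <= f2 else _invert_f_pairwise(y_lo, s_inf, n_star)
        if y_hi >= f_inf:
            hi, infinite = math.inf, True
        else:
            hi, infinite = _invert_f_pairwise(y_hi, s_inf, n_star), False
    elif mid in ("ebcm", "pairwise_poisson"):
        q = q_of(s_inf)
        if not n_star > q:
            raise ValueError(f"n_star must exceed q = {q:.6g}")
        f_star = float(f_ebcm(n_star, s_inf))
        y_lo, y_hi = f_star - epsilon, f_star + epsilon
        # f(n) = (n-1)/(n-q) is decreasing with closed-form inverse
        lo = (y_hi * q - 1.0) / (y_hi - 1.0)  # y_hi > f_star > 1
        if y_lo <= 1.0:
            hi, infinite = math.inf, True
        else:
            hi, infinite = (y_lo * q - 1.0) / (y_lo - 1.0), False
    else:
        raise ValueError(
            "epsilon solution set is defined for the pairwise and ebcm reductions; "
            "the sir observation curves coincide identically"
        )
    measure = math.inf if infinite else hi - lo
    return EpsilonSolutionSet(
        epsilon=epsilon,
        n_star=n_star,
        intervals=((lo, hi),),
        measure=measure,
        infinite=infinite,
    )


# -- (tau, gamma) at known n ---------------------------------------------------


def solve_tau_gamma_given_n(
    n: float, lam: float, s_inf: float, model_spec: ModelSpec, phi_S0: float = 1.0
) -> TauGammaSolution:
    """Solve the 2x2 linear system for (tau, gamma) when n is known.

    The eigenvalue equation tau*l(n) - gamma = lam and the final-size
    equation are both linear in (tau, gamma), so apart from exceptional
    (singular) cases the pair is uniquely determined.
    """
    if not (0.0 < s_inf < 1.0):
        raise ValueError(f"s_inf must lie in (0, 1), got {s_inf}")
    ls = math.log(s_inf)
    mid = model_spec.model_id
    slope = model_spec.eigen_slope(n)
    if mid == "sir":
        row2 = (n * (1.0 - s_inf), ls)
    elif mid == "pairwise_binomial":
        row2 = (
            s_inf - s_inf ** (2.0 / n),
            s_inf ** (1.0 / n) - s_inf ** (2.0 / n),
        )
    else:  # pairwise_poisson / ebcm
        row2 = (n * phi_S0 * s_inf - ls - n, -ls)
    A = np.array([[slope, -1.0], row2], dtype=float)
    det = float(np.linalg.det(A))
    scale = float(np.max(np.abs(A)))
    if abs(det) <= 1e-12 * scale * scale:
        raise SingularSystemError(
            f"(tau, gamma) system singular at n={n}, s_inf={s_inf} (det={det:.3e})"
        )
    tau, gamma = np.linalg.solve(A, np.array([lam, 0.0]))
    return TauGammaSolution(tau=float(tau), gamma=float(gamma), determinant=det)
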