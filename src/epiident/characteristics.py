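"""Leading eigenvalues and implicit final-size equations for the mean-field models.

Every model considered here linearises around its disease-free steady
state to a leading eigenvalue of the form

    lambda = tau * l(n) - gamma,

with l(n) = n (sir), n-2 (pairwise, kappa=(n-1)/n) or n-1 (pairwise with
kappa=1 and EBCM).  Each model also admits an implicit equation for the
final susceptible fraction s_inf = S_inf/N, solved here with a bracketing
Brent root-finder.  A finite-difference Jacobian at the disease-free state
provides an independent numerical check of the closed-form eigenvalues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from epiident.epidemic_models import (
    EpidemicParams,
    InitialCondition,
    ModelSpec,
    default_initial_condition,
    rhs_ebcm,
    rhs_pairwise,
    rhs_sir,
)

__all__ = [
    "ObservedSummaries",
    "FinalSizeResult",
    "ThresholdError",
    "leading_eigenvalue",
    "numerical_leading_eigenvalue",
    "final_size_sir",
    "final_size_pairwise",
    "final_size_pairwise_k1",
    "final_size_ebcm",
    "final_size",
]

# bracket for the nontrivial root: excludes s = 1, which always solves the
# disease-free-initialised equations
_BRACKET_LO = 1e-12
_BRACKET_DELTA = 1e-9
_ROOT_TOL = 1e-12


class ThresholdError(ValueError):
    """Raised when a nontrivial final-size root is requested on the wrong side
    of the epidemic threshold tau*l(n) = gamma."""


@dataclass(frozen=True)
class ObservedSummaries:
    """The measured pair the inverse problem consumes.

    lam : early growth rate / leading eigenvalue (1/day)
    s_inf : final susceptible fraction in (0, 1]
    """

    lam: float
    s_inf: float

    def __post_init__(self) -> None:
        if not (0.0 < self.s_inf <= 1.0):
            raise ValueError(f"s_inf must lie in (0, 1], got {self.s_inf}")

    @property
    def r_inf(self) -> float:
        """Final epidemic size fraction, 1 - s_inf."""
        return 1.0 - self.s_inf


@dataclass(frozen=True)
class FinalSizeResult:
    """Root of a final-size equation.

    s_inf : final susceptible fraction
    theta_inf : EBCM fixed point (None for other models)
    residual : value of the implicit equation at the returned root
    bracket : interval the root was isolated in (None when trivial)
    """

    s_inf: float
    theta_inf: float | None = None
    residual: float = 0.0
    bracket: tuple[float, float] | None = None

    @property
    def r_inf(self) -> float:
        return 1.0 - self.s_inf


# -- eigenvalues ---------------------------------------------------------------


def leading_eigenvalue(model_spec: ModelSpec, params: EpidemicParams) -> float:
    """Closed-form leading eigenvalue lambda = tau*l(n) - gamma at the DFE."""
    return params.tau * model_spec.eigen_slope(params.n) - params.gamma


def numerical_leading_eigenvalue(
    model_spec: ModelSpec, params: EpidemicParams, step: float = 1e-6
) -> float:
    """Leading eigenvalue from a finite-difference Jacobian at the disease-free state.

    The Jacobian of the model's vector field is evaluated by central
    differences at the disease-free steady state and restricted to the
    infection subsystem (I for sir; [I], [SI] for pairwise), whose dominant
    eigenvalue governs early exponential growth.  For the EBCM the scalar
    derivative of the theta equation at theta = 1 is returned.  Serves as
    an independent oracle for `leading_eigenvalue`.
    """
    if not step > 0:
        raise ValueError("finite-difference step must be positive")
    N, n = params.N, params.n
    mid = model_spec.model_id

    if mid == "ebcm":
        init = InitialCondition("ebcm", theta0=1.0, phi_S0=1.0, phi_R0=0.0)
        h = step
        # one-sided second-order stencil staying inside theta <= 1
        deriv = (
            3.0 * rhs_ebcm(1.0, params, init)
            - 4.0 * rhs_ebcm(1.0 - h, params, init)
            + rhs_ebcm(1.0 - 2.0 * h, params, init)
        ) / (2.0 * h)
        if not math.isfinite(deriv):
            raise FloatingPointError("degenerate finite-difference step for ebcm")
        return deriv

    if mid == "sir":
        dfe = np.array([N, 0.0])
        infected = [1]

        def f(y):
            return np.array(rhs_sir(y, params))

    else:
        dfe = np.array([N, 0.0, n * N, 0.0])
        infected = [1, 3]
        variant = "binomial" if mid == "pairwise_binomial" else "poisson"

        def f(y):
            return np.array(rhs_pairwise(y, params, variant))

    h = step * max(1.0, N)
    dim = len(dfe)
    jac = np.empty((dim, dim))
    for j in range(dim):
        e = np.zeros(dim)
        e[j] = h
        jac[:, j] = (f(dfe + e) - f(dfe - e)) / (2.0 * h)
    # the S (and SS) directions are neutral at the DFE; early growth is
    # governed by the infection block ([I], [SI])
    block = jac[np.ix_(infected, infected)]
    eigs = np.linalg.eigvals(block)
    if not np.all(np.isfinite(eigs)):
        raise FloatingPointError("degenerate finite-difference Jacobian")
    return float(np.max(eigs.real))


# -- final sizes ---------------------------------------------------------------


def _solve_bracketed(func, lo: float, hi: float, what: str) -> tuple[float, float]:
    flo, fhi = func(lo), func(hi)
    if flo == 0.0:
        return lo, 0.0
    if fhi == 0.0:
        return hi, 0.0
    if np.sign(flo) == np.sign(fhi):
        raise ThresholdError(
            f"no sign change for {what} on [{lo:g}, {hi:g}] "
            f"(f(lo)={flo:.3e}, f(hi)={fhi:.3e}); check the threshold condition"
        )
    root = brentq(func, lo, hi, xtol=_ROOT_TOL, rtol=8.9e-16)
    return float(root), float(func(root))


def final_size_sir(params: EpidemicParams, s0: float = 1.0) -> FinalSizeResult:
    """Final size of the classic SIR model.

    Solves R_inf = N - S0*exp(-tau*n*R_inf/(N*gamma)) for the final
    attack fraction r_inf; with s0 = 1 this is the classic relation
    tau*n*r_inf + gamma*ln(1-r_inf) = 0.  Subcritical (tau*n <= gamma)
    with s0 = 1 returns r_inf = 0.
    """
    if not (0.0 < s0 <= 1.0):
        raise ValueError(f"s0 must lie in (0, 1], got {s0}")
    R0 = params.tau * params.n / params.gamma

    def eqn(r):  # r = R_inf/N
        return r - (1.0 - s0 * math.exp(-R0 * r))

    if s0 == 1.0 and R0 <= 1.0:
        return FinalSizeResult(s_inf=1.0, residual=0.0)
    lo = _BRACKET_LO if s0 == 1.0 else 0.0
    # r is bounded above by 1 - s0*exp(-R0)
    root, res = _solve_bracketed(eqn, lo, 1.0 - _BRACKET_DELTA, "sir final size")
    return FinalSizeResult(s_inf=1.0 - root, residual=res, bracket=(lo, 1.0))


def _pairwise_fs_eqn(s: float, tau: float, gamma: float, n: float) -> float:
    """tau*(s - s^(2/n)) + gamma*(s^(1/n) - s^(2/n)), written via expm1 to
    survive the n -> 2 and s -> 1 cancellations."""
    ls = math.log(s)
    s1 = math.exp(ls / n)
    # s - s^(2/n) = s * -expm1((2/n - 1) ls);  s^(1/n) - s^(2/n) = s^(1/n)*-expm1(ls/n)
    return -tau * s * math.expm1((2.0 / n - 1.0) * ls) - gamma * s1 * math.expm1(
        ls / n
    )


def final_size_pairwise(params: EpidemicParams, S0: float | None = None) -> FinalSizeResult:
    """Final size of the binomial-closure (kappa=(n-1)/n) pairwise model.

    With S0 = N this solves tau*(s - s^(2/n)) + gamma*(s^(1/n) - s^(2/n)) = 0
    for the nontrivial root s_inf in (0, 1); subcritical
    (tau*(n-2) <= gamma) returns s_inf = 1.  With general S0 the full
    implicit relation
    N*(tau+gamma)*S_inf^(2/n) = N*gamma*S0^(1/n)*S_inf^(1/n) + tau*S_inf*S0^(2/n)
    is solved literally.
    """
    tau, gamma, n, N = params.tau, params.gamma, params.n, params.N
    if S0 is None or S0 == N:
        if tau * (n - 2.0) <= gamma:
            return FinalSizeResult(s_inf=1.0, residual=0.0)
        lo, hi = _BRACKET_LO, 1.0 - _BRACKET_DELTA
        root, res = _solve_bracketed(
            lambda s: _pairwise_fs_eqn(s, tau, gamma, n),
            lo,
            hi,
            "pairwise final size",
        )
        return FinalSizeResult(s_inf=root, residual=res, bracket=(lo, hi))
    if not (0.0 < S0 <= N):
        raise ValueError(f"S0 must lie in (0, N], got {S0}")

    def eqn(S):
        return (
            N * (tau + gamma) * S ** (2.0 / n)
            - N * gamma * S0 ** (1.0 / n) * S ** (1.0 / n)
            - tau * S * S0 ** (2.0 / n)
        )

    lo, hi = _BRACKET_LO * N, S0 * (1.0 - _BRACKET_DELTA)
    root, res = _solve_bracketed(eqn, lo, hi, "pairwise final size (general S0)")
    return FinalSizeResult(s_inf=root / N, residual=res, bracket=(lo / N, hi / N))


def final_size_ebcm(params: EpidemicParams, phi_S0: float = 1.0) -> FinalSizeResult:
    """Final size of the EBCM with Poisson PGF.

    Solves (tau+gamma)*theta_inf - gamma - tau*phi_S0*exp(n(theta_inf-1)) = 0
    for the smallest admissible root and returns
    s_inf = exp(n(theta_inf - 1)).  Subcritical with phi_S0 = 1 returns
    theta_inf = 1, s_inf = 1.
    """
    if not (0.0 < phi_S0 <= 1.0):
        raise ValueError(f"phi_S0 must lie in (0, 1], got {phi_S0}")
    tau, gamma, n = params.tau, params.gamma, params.n

    def eqn(theta):
        return (tau + gamma) * theta - gamma - tau * phi_S0 * math.exp(
            n * (theta - 1.0)
        )

    if phi_S0 == 1.0 and tau * (n - 1.0) <= gamma:
        return FinalSizeResult(s_inf=1.0, theta_inf=1.0, residual=0.0)
    lo, hi = _BRACKET_LO, 1.0 - _BRACKET_DELTA
    theta, res = _solve_bracketed(eqn, lo, hi, "ebcm final size")
    return FinalSizeResult(
        s_inf=math.exp(n * (theta - 1.0)),
        theta_inf=theta,
        residual=res,
        bracket=(lo, hi),
    )


def final_size_pairwise_k1(
    params: EpidemicParams, init: InitialCondition | None = None
) -> FinalSizeResult:
    """Final size of the kappa=1 (Poisson-closure) pairwise model.

    The conserved-quantity reduction of the kappa=1 system gives an implicit
    relation between S_inf and the initial pair/node counts; with the
    disease-free initial condition ([S](0)=N, [SS](0)=nN, [SI](0)=0) it is
    identical to the EBCM relation with phi_S(0) = 1.
    """
    tau, gamma, n, N = params.tau, params.gamma, params.n, params.N
    if init is None:
        init = InitialCondition(
            "pairwise_poisson", S0=N, I0=0.0, SS0=n * N, SI0=0.0
        )
    if init.S0 is None or init.S0 <= 0:
        raise ValueError("initial susceptible count [S](0) must be positive")
    S0, SS0, SI0 = init.S0, init.SS0, init.SI0

    dfe_like = S0 == N and SI0 == 0.0 and abs(SS0 - n * N) < 1e-9 * max(1.0, n * N)
    if dfe_like and tau * (n - 1.0) <= gamma:
        return FinalSizeResult(s_inf=1.0, residual=0.0)

    def eqn(S):
        # gamma*S*ln(S/S0) - tau*( (SS0/S0^2)*S^2 - S*ln(S/S0) - (SI0/S0 + SS0/S0)*S )
        lr = math.log(S / S0)
        return gamma * S * lr - tau * (
            SS0 / S0**2 * S * S - S * lr - (SI0 / S0 + SS0 / S0) * S
        )

    lo, hi = _BRACKET_LO * N, S0 * (1.0 - _BRACKET_DELTA)
    root, res = _solve_bracketed(eqn, lo, hi, "pairwise kappa=1 final size")
    return FinalSizeResult(s_inf=root / N, residual=res, bracket=(lo / N, hi / N))


def final_size(
    model_spec: ModelSpec, params: EpidemicParams, **kwargs
) -> FinalSizeResult:
    """Dispatch to the model-specific final-size solver."""
    mid = model_spec.model_id
    if mid == "sir":
        return final_size_sir(params, **kwargs)
    if mid == "pairwise_binomial":
        return final_size_pairwise(params, **kwargs)
    if mid == "pairwise_poisson":
        return final_size_pairwise_k1(params, **kwargs)
    return final_size_ebcm(params, **kwargs)
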