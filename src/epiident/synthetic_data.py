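"""Synthetic "measured" epidemics for the inverse problem.

Observations come in two flavours:

* analytic — the leading eigenvalue and the root of the model's implicit
  final-size equation, exact fixed points of the inverse problem;
* trajectory-derived — the growth rate estimated from the exponential
  phase of the daily-new-cases series and the final size read off a run
  integrated to quiescence.

An optional noise model perturbs the analytic pair: the growth rate
multiplicatively (relative Gaussian), the final susceptible fraction
additively (absolute Gaussian, clipped to (0, 1)).  All randomness flows
through a single seeded generator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from epiident.epidemic_models import (
    EpidemicParams,
    ModelSpec,
    Trajectory,
)
from epiident.characteristics import (
    ObservedSummaries,
    final_size,
    leading_eigenvalue,
)

__all__ = [
    "NoiseSpec",
    "ScenarioFixture",
    "generate_observation",
    "estimate_growth_rate",
    "estimate_final_size",
    "make_fixture_suite",
    "save_fixture_suite",
]

_S_CLIP = 1e-6  # perturbed s_inf is clipped to [_S_CLIP, 1 - _S_CLIP]


@dataclass(frozen=True)
class NoiseSpec:
    """Perturbation model for the observed (lam, s_inf) pair.

    lam is scaled by (1 + xi), xi ~ N(0, lam_rel_sd); s_inf is shifted by
    zeta ~ N(0, s_inf_abs_sd) and clipped into (0, 1).  The same seed
    always reproduces the same draws.
    """

    lam_rel_sd: float = 0.02
    s_inf_abs_sd: float = 0.01
    seed: int = 0


@dataclass(frozen=True)
class ScenarioFixture:
    """A self-contained test scenario: true parameters plus observations."""

    label: str
    model_id: str
    params: EpidemicParams
    I0: float
    supercritical: bool
    observation: ObservedSummaries
    noisy_observation: ObservedSummaries
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "model_id": self.model_id,
            "params": self.params.to_dict(),
            "I0": self.I0,
            "supercritical": self.supercritical,
            "observation": {
                "lam": self.observation.lam,
                "s_inf": self.observation.s_inf,
            },
            "noisy_observation": {
                "lam": self.noisy_observation.lam,
                "s_inf": self.noisy_observation.s_inf,
            },
            "provenance": self.provenance,
        }


def generate_observation(
    model_spec: ModelSpec,
    params: EpidemicParams,
    noise: NoiseSpec | None = None,
) -> ObservedSummaries:
    """Noiseless (or noise-perturbed) analytic observation pair.

    lam comes from the closed-form leading eigenvalue and s_inf from the
    model's final-size solver; a subcritical parameter set yields
    s_inf = 1 (no outbreak)."""
    lam = leading_eigenvalue(model_spec, params)
    s_inf = final_size(model_spec, params).s_inf
    if noise is None:
        return ObservedSummaries(lam=lam, s_inf=s_inf)
    rng = np.random.default_rng(noise.seed)
    lam_noisy = lam * (1.0 + rng.normal(0.0, noise.lam_rel_sd))
    s_noisy = float(
        np.clip(
            s_inf + rng.normal(0.0, noise.s_inf_abs_sd), _S_CLIP, 1.0 - _S_CLIP
        )
    )
    return ObservedSummaries(lam=lam_noisy, s_inf=s_noisy)


def _auto_window(traj: Trajectory) -> tuple[float, float]:
    """Default exponential-phase window: days with prevalence in [10, 0.01*N].

    Falls back to the first fifteen days with positive daily counts when
    the epidemic never reaches 10 concurrent cases (small or subcritical
    runs)."""
    N = traj.params.N
    days = traj.day_bins
    prev_days = np.interp(days, traj.times, traj.prevalence)
    # keep the window before the prevalence peak: the same band is crossed
    # again on the way down, where growth is no longer exponential
    mask = (prev_days >= 10.0) & (prev_days <= 0.01 * N)
    mask &= days <= days[np.argmax(prev_days)]
    if mask.sum() >= 3:
        sel = days[mask]
        return float(sel[0]), float(sel[-1])
    positive = traj.day_bins[1:][traj.daily_new_cases > 0]
    if positive.size < 2:
        raise ValueError("no usable exponential-phase window in trajectory")
    return float(positive[0]), float(min(positive[0] + 15.0, positive[-1]))


def estimate_growth_rate(
    traj: Trajectory, fit_window: tuple[float, float] | None = None
) -> float:
    """Growth-rate estimate: least-squares slope of log(daily new cases) vs time.

    The window defaults to the exponential phase (prevalence between 10
    and 1% of N).  Nonpositive counts inside the window are an error —
    the log-linear fit is meaningless there."""
    if fit_window is None:
        fit_window = _auto_window(traj)
    t0, t1 = fit_window
    mids = traj.day_bins[1:]  # label each bin by its right edge
    mask = (mids >= t0) & (mids <= t1)
    if mask.sum() < 2:
        raise ValueError(f"fit window [{t0}, {t1}] contains fewer than 2 day bins")
    cases = traj.daily_new_cases[mask]
    if np.any(cases <= 0):
        raise ValueError("nonpositive daily counts inside the fit window")
    slope, _ = np.polyfit(mids[mask], np.log(cases), 1)
    return float(slope)


def estimate_final_size(traj: Trajectory) -> float:
    """Final susceptible fraction S(t_end)/N (EBCM: psi(theta(t_end))).

    Warns if the trajectory has not reached quiescence (prevalence below
    1e-8*N), in which case the estimate is biased upward."""
    if traj.prevalence[-1] > 1e-8 * traj.params.N * (1.0 + 1e-6):
        warnings.warn(
            "trajectory not integrated to quiescence; final-size estimate "
            f"is biased (prevalence {traj.prevalence[-1]:.3g})",
            stacklevel=2,
        )
    return traj.final_susceptible_fraction()


# -- deterministic fixture suite ----------------------------------------------


def make_fixture_suite(seed: int = 0) -> list[ScenarioFixture]:
    """Deterministic scenario suite covering all four models, both sides of
    the epidemic threshold, the baseline indistinguishability experiment
    (tau=gamma=1/7, n=6, N=1e4) and the curve-family parameter settings
    (pairwise tau in {0.26, 0.33, 0.47} at gamma=1; EBCM tau in
    {0.03, 0.045, 0.07} at gamma=1/7)."""
    g7 = 1.0 / 7.0
    N = 10_000.0
    scenarios: list[tuple[str, str, EpidemicParams]] = [
        ("sir_supercritical", "sir", EpidemicParams(tau=2.5 * g7 / 5.0, gamma=g7, n=5.0, N=N)),
        ("sir_subcritical", "sir", EpidemicParams(tau=0.8 * g7 / 5.0, gamma=g7, n=5.0, N=N)),
        ("pairwise_baseline", "pairwise_binomial", EpidemicParams(tau=g7, gamma=g7, n=6.0, N=N)),
        ("pairwise_subcritical", "pairwise_binomial", EpidemicParams(tau=0.03, gamma=g7, n=6.0, N=N)),
        ("poisson_supercritical", "pairwise_poisson", EpidemicParams(tau=0.045, gamma=g7, n=6.0, N=N)),
        ("poisson_subcritical", "pairwise_poisson", EpidemicParams(tau=0.02, gamma=g7, n=6.0, N=N)),
        ("ebcm_subcritical", "ebcm", EpidemicParams(tau=0.02, gamma=g7, n=6.0, N=N)),
    ]
    for tau in (0.26, 0.33, 0.47):
        scenarios.append(
            (f"pairwise_family_tau{tau}", "pairwise_binomial",
             EpidemicParams(tau=tau, gamma=1.0, n=6.0, N=N))
        )
    for tau in (0.03, 0.045, 0.07):
        scenarios.append(
            (f"ebcm_family_tau{tau}", "ebcm",
             EpidemicParams(tau=tau, gamma=g7, n=6.0, N=N))
        )

    child_seeds = np.random.SeedSequence(seed).generate_state(len(scenarios))
    fixtures = []
    for (label, model_id, params), sub in zip(scenarios, child_seeds):
        spec = ModelSpec(model_id)
        lam = leading_eigenvalue(spec, params)
        noiseless = generate_observation(spec, params)
        noisy = generate_observation(
            spec, params, NoiseSpec(seed=int(sub) % 2**31)
        )
        fixtures.append(
            ScenarioFixture(
                label=label,
                model_id=model_id,
                params=params,
                I0=1.0,
                supercritical=lam > 0,
                observation=noiseless,
                noisy_observation=noisy,
                provenance={"generator": "make_fixture_suite", "seed": seed},
            )
        )
    return fixtures


def save_fixture_suite(fixtures: list[ScenarioFixture], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([f.to_dict() for f in fixtures], indent=2)
    )
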