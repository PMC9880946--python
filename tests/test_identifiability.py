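"""The (n, tau) inverse problem: curves, intersection, the reduced f and
the epsilon-band solution set."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epiident import (
    EpidemicParams,
    ModelSpec,
    NoIntersectionError,
    ObservedSummaries,
    StructurallyUnidentifiableError,
    build_curves,
    epsilon_solution_set,
    f_ebcm,
    f_limits_pairwise,
    f_pairwise,
    final_size_pairwise,
    generate_observation,
    intersect_curves,
    scan_monotonicity,
    solve_tau_gamma_given_n,
    tau_from_eigenvalue,
    tau_from_final_size,
)
from epiident.identifiability import SingularSystemError, q_of

from conftest import GAMMA7, supercritical_params

PW = ModelSpec("pairwise_binomial")
EB = ModelSpec("ebcm")
SIRM = ModelSpec("sir")


class TestTauFromEigenvalue:
    def test_alternate_degree_rate_pair(self):
        # lam measured from the (n=6, tau=gamma=1/7) baseline, inverted at n=8.46
        tau = tau_from_eigenvalue(8.46, 0.4287, 0.1429, PW)
        assert tau == pytest.approx(0.0885, abs=5e-4)

    def test_round_trip_through_eigenvalue(self):
        p = supercritical_params("pairwise_binomial")
        lam = p.tau * (p.n - 2.0) - p.gamma
        assert tau_from_eigenvalue(p.n, lam, p.gamma, PW) == pytest.approx(p.tau)

    def test_strictly_decreasing_in_n(self):
        n = np.linspace(2.5, 50.0, 100)
        tau = tau_from_eigenvalue(n, 0.3, GAMMA7, PW)
        assert np.all(np.diff(tau) < 0)

    @pytest.mark.parametrize("spec, bad_n", [(PW, 2.0), (EB, 1.0), (SIRM, 0.0)])
    def test_domain_error_at_singularity(self, spec, bad_n):
        with pytest.raises(ValueError):
            tau_from_eigenvalue(bad_n, 0.3, GAMMA7, spec)


class TestTauFromFinalSize:
    def test_round_trip_with_final_size_solver(self):
        p = supercritical_params("pairwise_binomial", r0_equiv=2.5)
        s = final_size_pairwise(p).s_inf
        assert tau_from_final_size(p.n, s, p.gamma, PW) == pytest.approx(
            p.tau, abs=1e-8
        )

    def test_sir_pins_down_only_the_product(self):
        n = np.linspace(1.0, 40.0, 50)
        tau = tau_from_final_size(n, 0.2, GAMMA7, SIRM)
        assert np.ptp(tau * n) < 1e-12 * np.max(tau * n)

    def test_boundary_s_inf_one_is_undefined(self):
        with pytest.raises(ValueError):
            tau_from_final_size(6.0, 1.0, GAMMA7, EB)

    def test_ebcm_undefined_below_q(self):
        s = 0.4606
        with pytest.raises(ValueError):
            tau_from_final_size(q_of(s) * 0.99, s, GAMMA7, EB)


class TestBuildAndIntersectCurves:
    def test_sir_curves_coincide_structural_unidentifiability(self):
        p = supercritical_params("sir", r0_equiv=2.5)
        obs = generate_observation(SIRM, p)
        ceig, cfs = build_curves(SIRM, obs, p.gamma, np.linspace(1.0, 50.0, 200))
        assert np.max(np.abs(ceig.tau - cfs.tau)) < 1e-10 * np.max(ceig.tau)
        with pytest.raises(StructurallyUnidentifiableError):
            intersect_curves((ceig, cfs))

    def test_pairwise_single_sign_change(self):
        p = EpidemicParams(tau=0.26, gamma=1.0, n=6.0)
        obs = generate_observation(PW, p)
        ceig, cfs = build_curves(PW, obs, p.gamma, np.geomspace(2.1, 100.0, 300))
        diff = ceig.tau - cfs.tau
        sign_changes = np.sum(np.diff(np.sign(diff)) != 0)
        assert sign_changes == 1

    def test_inconsistent_observation_has_no_intersection(self):
        # lam too large for any n given this final size: (lam+gamma)/gamma
        # above the whole range of f
        s = 0.9
        f2, f_inf = f_limits_pairwise(s)
        lam = GAMMA7 * (f_inf + 0.5) - GAMMA7
        obs = ObservedSummaries(lam=lam, s_inf=s)
        curves = build_curves(PW, obs, GAMMA7)
        with pytest.raises(NoIntersectionError) as err:
            intersect_curves(curves)
        assert err.value.min_gap > 0

    @pytest.mark.parametrize("spec", [PW, EB], ids=lambda s: s.model_id)
    def test_noiseless_recovery_across_parameter_grid(self, spec):
        # simulate -> measure (noiselessly) -> build curves -> intersect
        for r0_equiv in (1.5, 2.5, 3.5):
            for n_true in (4.0, 6.0, 9.0):
                p = supercritical_params(spec.model_id, r0_equiv, n=n_true)
                obs = generate_observation(spec, p)
                result = intersect_curves(build_curves(spec, obs, p.gamma))
                assert result.n_star == pytest.approx(n_true, rel=1e-4)
                assert result.tau_star == pytest.approx(p.tau, rel=1e-4)
                assert not result.multiple

    def test_small_observation_error_shifts_n_star_substantially(self):
        p = supercritical_params("pairwise_binomial")
        obs = generate_observation(PW, p)
        perturbed = ObservedSummaries(lam=obs.lam, s_inf=obs.s_inf * 1.01)
        n_star = intersect_curves(build_curves(PW, perturbed, p.gamma)).n_star
        rel_shift = abs(n_star - p.n) / p.n
        # the relative error is amplified: a 1% final-size error moves the
        # degree estimate by several percent
        assert rel_shift > 2 * 0.01


class TestReducedFunctionPairwise:
    def test_limits_at_s09(self):
        f2, f_inf = f_limits_pairwise(0.9)
        assert f2 == pytest.approx(1.027, abs=5e-4)
        assert f_inf == pytest.approx(1.054, abs=5e-4)
        assert f_inf - f2 == pytest.approx(0.027, abs=1e-3)

    def test_interior_value_lies_between_limits(self):
        f2, f_inf = f_limits_pairwise(0.9)
        val = f_pairwise(6.0, 0.9)
        assert val == pytest.approx(1.04468, abs=1e-4)
        assert f2 < val < f_inf

    def test_numerical_limits_match_closed_forms(self):
        for s in (0.3, 0.6, 0.9):
            f2, f_inf = f_limits_pairwise(s)
            assert abs(f_pairwise(2.0 + 1e-8, s) - f2) < 1e-6
            assert abs(f_inf - f_pairwise(1e8, s)) < 1e-6

    def test_limits_tend_to_one_as_s_tends_to_one(self):
        f2, f_inf = f_limits_pairwise(1.0 - 1e-9)
        assert f2 == pytest.approx(1.0, abs=1e-6)
        assert f_inf == pytest.approx(1.0, abs=1e-6)

    @given(s=st.floats(0.11, 0.99), n=st.floats(2.01, 500.0))
    def test_range_containment_above_threshold(self, s, n):
        f2, f_inf = f_limits_pairwise(s)
        assert f2 - 1e-9 <= f_pairwise(n, s) <= f_inf + 1e-9

    def test_reduction_reproduces_curve_system(self):
        # gamma*f(n) - gamma fed back through the eigenvalue inversion must
        # reproduce the final-size inversion exactly, for all n
        s, gamma = 0.5036, 1.0
        n = np.geomspace(2.05, 400.0, 200)
        lam_implied = gamma * f_pairwise(n, s) - gamma
        tau_eig = (lam_implied + gamma) / (n - 2.0)
        tau_fs = tau_from_final_size(n, s, gamma, PW)
        np.testing.assert_allclose(tau_eig, tau_fs, rtol=1e-12)


class TestReducedFunctionEbcm:
    def test_value_at_n10_s09(self):
        assert f_ebcm(10.0, 0.9) == pytest.approx(1.006, abs=5e-4)

    def test_q_matches_pairwise_infinite_limit(self):
        # q = ln(s)/(s-1) is the same expression as the pairwise f_inf
        assert q_of(0.9) == pytest.approx(f_limits_pairwise(0.9)[1], abs=1e-14)
        assert q_of(0.9) == pytest.approx(1.0536, abs=1e-4)

    def test_decreases_to_one_at_large_n(self):
        n = np.geomspace(2.0, 1e6, 200)
        vals = f_ebcm(n, 0.9)
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] == pytest.approx(1.0, abs=1e-5)

    def test_domain_error_at_or_below_q(self):
        with pytest.raises(ValueError):
            f_ebcm(q_of(0.9), 0.9)

    def test_poisson_closure_curve_equals_ebcm_curve(self):
        n = np.geomspace(2.0, 100.0, 50)
        tau_pp = tau_from_final_size(n, 0.4606, GAMMA7, ModelSpec("pairwise_poisson"))
        tau_eb = tau_from_final_size(n, 0.4606, GAMMA7, EB)
        np.testing.assert_array_equal(tau_pp, tau_eb)


class TestMonotonicityScan:
    def test_empirical_threshold_below_claimed_bound(self):
        scan = scan_monotonicity()
        assert 0.0 < scan.monotone_threshold <= 0.1

    def test_verdicts_stable_under_grid_refinement(self):
        s_grid = np.arange(0.05, 0.95, 0.05)
        coarse = scan_monotonicity(s_grid, np.geomspace(2.0 + 1e-6, 1e3, 1000))
        fine = scan_monotonicity(s_grid, np.geomspace(2.0 + 1e-6, 1e3, 2000))
        np.testing.assert_array_equal(coarse.increasing, fine.increasing)

    def test_s09_is_increasing_and_bounded(self):
        n = np.geomspace(2.0 + 1e-6, 1e3, 2000)
        vals = f_pairwise(n, 0.9)
        f2, f_inf = f_limits_pairwise(0.9)
        assert np.all(np.diff(vals) > 0)
        assert f2 < vals[0] and vals[-1] < f_inf


class TestEpsilonSolutionSet:
    s = 0.9098  # final size of the (tau=0.26, gamma=1, n=6) pairwise epidemic

    def test_band_wider_than_range_covers_half_line(self):
        f2, f_inf = f_limits_pairwise(self.s)
        es = epsilon_solution_set(PW, self.s, 6.0, (f_inf - f2) * 1.01)
        assert es.infinite and math.isinf(es.measure)
        assert es.intervals[0][0] == 2.0

    def test_band_reaching_upper_limit_gives_half_line(self):
        f_star = f_pairwise(6.0, self.s)
        f_inf = f_limits_pairwise(self.s)[1]
        es = epsilon_solution_set(PW, self.s, 6.0, (f_inf - f_star) * 1.001)
        (lo, hi), = es.intervals
        assert 2.0 < lo < 6.0 and math.isinf(hi) and es.infinite

    def test_small_band_shrinks_to_point(self):
        widths = []
        for eps in (1e-3, 1e-5, 1e-7):
            es = epsilon_solution_set(PW, self.s, 6.0, eps)
            assert not es.infinite
            (lo, hi), = es.intervals
            assert lo < 6.0 < hi
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_measure_nondecreasing_in_epsilon(self):
        epsilons = np.geomspace(1e-6, 1e-1, 12)
        measures = [
            epsilon_solution_set(PW, self.s, 6.0, float(e)).measure for e in epsilons
        ]
        assert all(b >= a for a, b in zip(measures, measures[1:]))

    def test_infinite_iff_band_reaches_bounded_limit(self):
        f_star = f_pairwise(6.0, self.s)
        f_inf = f_limits_pairwise(self.s)[1]
        gap = f_inf - f_star
        assert not epsilon_solution_set(PW, self.s, 6.0, gap * 0.99).infinite
        assert epsilon_solution_set(PW, self.s, 6.0, gap * 1.01).infinite

    def test_ebcm_closed_form_inversion(self):
        s = 0.9217
        n_star = 6.0
        f_star = f_ebcm(n_star, s)
        es = epsilon_solution_set(EB, s, n_star, (f_star - 1.0) * 1.01)
        assert es.infinite
        (lo, hi), = es.intervals
        assert q_of(s) < lo < n_star
        # finite case: endpoints actually achieve |f - f*| = eps
        eps = (f_star - 1.0) * 0.3
        es2 = epsilon_solution_set(EB, s, n_star, eps)
        (lo2, hi2), = es2.intervals
        assert f_ebcm(lo2, s) == pytest.approx(f_star + eps, abs=1e-9)
        assert f_ebcm(hi2, s) == pytest.approx(f_star - eps, abs=1e-9)


class TestSolveTauGammaGivenN:
    def test_sir_hand_worked_example(self):
        sol = solve_tau_gamma_given_n(10.0, 0.5, 1.0 - 0.8926, SIRM)
        assert sol.tau == pytest.approx(0.0833, abs=2e-4)
        assert sol.gamma == pytest.approx(1.0 / 3.0, abs=1e-3)

    @pytest.mark.parametrize("spec", [SIRM, PW, EB], ids=lambda s: s.model_id)
    def test_round_trip_recovery(self, spec):
        p = supercritical_params(spec.model_id, r0_equiv=2.0)
        obs = generate_observation(spec, p)
        sol = solve_tau_gamma_given_n(p.n, obs.lam, obs.s_inf, spec)
        assert sol.tau == pytest.approx(p.tau, rel=1e-8)
        assert sol.gamma == pytest.approx(p.gamma, rel=1e-8)

    def test_degenerate_observation_detected(self):
        # s_inf -> 1 collapses the final-size row to zero: singular system
        with pytest.raises(SingularSystemError):
            solve_tau_gamma_given_n(10.0, 0.5, 1.0 - 1e-13, SIRM)
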