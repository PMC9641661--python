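"""Extended model: Hill algebra, fixed points, stability, switching."""

from dataclasses import replace

import numpy as np
import pytest

from her6switch.adaptation import (
    DomainError,
    rhs_basic,
    simulate_basic,
    steady_state_h,
    steady_state_X,
)
from her6switch.extended import (
    HillSpec,
    check_parameter_feasibility,
    classify_outcome,
    find_switching_threshold,
    full_fixed_points,
    hill_activating,
    hill_repressing,
    jacobian_extended,
    rhs_extended,
    sample_feasible_parameters,
    simulate_extended,
    y_subsystem_fixed_points,
)
from her6switch.profiles import make_constant, make_steps


class TestHill:
    def test_half_maximal_point(self):
        spec = HillSpec(n=4, p0=0.5)
        assert hill_activating(0.5, spec) == pytest.approx(0.5)
        assert hill_repressing(0.5, spec) == pytest.approx(0.5)

    def test_limits(self):
        spec = HillSpec(n=4, p0=1.0)
        assert hill_activating(0.0, spec) == 0.0
        assert hill_repressing(0.0, spec) == 1.0
        assert hill_activating(100.0, spec) == pytest.approx(1.0, abs=1e-8)
        assert hill_repressing(100.0, spec) == pytest.approx(0.0, abs=1e-8)

    def test_complement_identity(self, rng):
        for _ in range(50):
            spec = HillSpec(n=float(rng.uniform(1, 8)), p0=float(rng.uniform(0.1, 5)))
            p = float(rng.uniform(0, 10))
            assert hill_activating(p, spec) + hill_repressing(p, spec) == pytest.approx(
                1.0, abs=1e-15
            )

    def test_invalid_specs(self):
        with pytest.raises(DomainError):
            HillSpec(n=0.5, p0=1.0)
        with pytest.raises(DomainError):
            HillSpec(n=2.0, p0=0.0)


class TestRhsAndJacobian:
    def test_reduces_to_basic_model_at_Y_zero(self, ref_params):
        prof = make_constant(1.3, 0.0, 10.0)
        state = (0.8, 1.7, 0.0)
        ext = rhs_extended(state, 2.0, ref_params, prof)
        basic = rhs_basic(state[:2], 2.0, ref_params.basic, prof)
        np.testing.assert_allclose(ext[:2], basic, rtol=1e-15)

    def test_rhs_vanishes_at_reported_fixed_points(self, ref_params):
        prof = make_constant(1.0, 0.0, 1.0)
        for fp in full_fixed_points(ref_params, 1.0):
            res = rhs_extended(fp.state, 0.0, ref_params, prof)
            assert np.linalg.norm(res) < 1e-9

    def test_Y_production_suppressed_at_high_h(self, ref_params):
        # when Her6 sits at h* the Y branch is effectively off
        hstar = steady_state_h(ref_params.basic)
        prod = ref_params.y_production(hstar, 0.0)
        assert prod < 0.1 * ref_params.mu_Y  # tiny versus turnover scale

    def test_jacobian_matches_finite_differences(self, ref_params, rng):
        prof = make_constant(1.0, 0.0, 1.0)
        for _ in range(10):
            state = rng.uniform([0.05, 0.2, 0.0], [2.0, 3.0, 2.5])
            J = jacobian_extended(state, 1.0, ref_params)
            eps = 1e-7
            J_fd = np.empty((3, 3))
            for j in range(3):
                up = state.copy()
                dn = state.copy()
                up[j] += eps
                dn[j] -= eps
                J_fd[:, j] = (
                    rhs_extended(up, 0.0, ref_params, prof)
                    - rhs_extended(dn, 0.0, ref_params, prof)
                ) / (2 * eps)
            np.testing.assert_allclose(J, J_fd, rtol=1e-5, atol=1e-6)


class TestYSubsystem:
    def test_linear_case_single_root(self, ref_params):
        p = replace(ref_params, beta_Y=0.0)
        h = 0.3
        roots = y_subsystem_fixed_points(p, h)
        assert len(roots) == 1
        expected = p.alpha_Y * hill_repressing(h, p.hill_h_on_Y) / p.mu_Y
        assert roots[0][0] == pytest.approx(expected, rel=1e-9)
        assert roots[0][1] is True

    def test_monostable_high_with_repression_lifted(self, ref_params):
        """With Her6 absent only the self-activated high state remains, so a
        deep Her6 transient lets Y escape."""
        roots = y_subsystem_fixed_points(ref_params, 0.0)
        assert len(roots) == 1
        y, stable = roots[0]
        assert stable and y > ref_params.hill_Y_self.p0

    def test_bistable_at_intermediate_clamped_h(self, ref_params):
        hstar = steady_state_h(ref_params.basic)
        n_roots = {
            len(y_subsystem_fixed_points(ref_params, h))
            for h in np.linspace(0.3 * hstar, 0.7 * hstar, 30)
        }
        assert 3 in n_roots

    def test_single_low_root_at_h_star(self, ref_params):
        hstar = steady_state_h(ref_params.basic)
        roots = y_subsystem_fixed_points(ref_params, hstar)
        assert len(roots) == 1
        y, stable = roots[0]
        assert stable and y < ref_params.hill_Y_self.p0


class TestFullFixedPoints:
    def test_basic_limit(self, ref_params):
        p = replace(ref_params, beta_Y=0.0, alpha_Y=1e-8)
        fps = full_fixed_points(p, 1.0)
        assert len(fps) == 1
        hstar = steady_state_h(p.basic)
        assert fps[0].state[0] == pytest.approx(hstar, rel=1e-6)

    def test_reference_set_is_bistable(self, ref_params):
        fps = full_fixed_points(ref_params, 1.0)
        stable = [fp for fp in fps if fp.stable]
        unstable = [fp for fp in fps if not fp.stable]
        assert len(stable) == 2 and len(unstable) == 1
        hstar = steady_state_h(ref_params.basic)
        high = max(stable, key=lambda fp: fp.state[0])
        low = min(stable, key=lambda fp: fp.state[0])
        assert high.state[0] == pytest.approx(hstar, rel=0.01)
        assert high.state[2] < low.state[2]  # high-h state has low Y
        assert low.state[0] < 0.5 * hstar

    def test_stability_flag_matches_leading_eigenvalue(self, ref_params):
        for fp in full_fixed_points(ref_params, 1.0):
            assert fp.stable == (fp.leading_eigenvalue_real < 0)

    def test_stable_points_attract_small_perturbations(self, ref_params, fast_solver):
        t_grid = np.linspace(0.0, 60.0, 200)
        prof = make_constant(1.0, 0.0, t_grid[-1])
        for fp in full_fixed_points(ref_params, 1.0):
            if not fp.stable:
                continue
            init = np.array(fp.state) * np.array([1.01, 1.0, 1.01 if fp.state[2] > 0 else 1.0])
            traj = simulate_extended(ref_params, prof, t_grid, init=init, settings=fast_solver)
            np.testing.assert_allclose(traj.h[-1], fp.state[0], rtol=1e-3)

    def test_unstable_branch_separates_basins(self, ref_params, fast_solver):
        t_grid = np.linspace(0.0, 120.0, 300)
        prof = make_constant(1.0, 0.0, t_grid[-1])
        fps = full_fixed_points(ref_params, 1.0)
        unstable = next(fp for fp in fps if not fp.stable)
        stable_h = sorted(fp.state[0] for fp in fps if fp.stable)
        h_u, X_u, Y_u = unstable.state
        up = simulate_extended(
            ref_params, prof, t_grid, init=(h_u, X_u, Y_u * 1.05), settings=fast_solver
        )
        down = simulate_extended(
            ref_params, prof, t_grid, init=(h_u, X_u, Y_u * 0.95), settings=fast_solver
        )
        assert up.h[-1] == pytest.approx(stable_h[0], rel=1e-2)
        assert down.h[-1] == pytest.approx(stable_h[1], rel=1e-2)


class TestClassificationAndThreshold:
    def test_constant_input_from_high_state_is_adapted(self, ref_params, fast_solver):
        prof = make_constant(1.0, 0.0, 80.0)
        traj = simulate_extended(
            ref_params, prof, np.linspace(0, 80, 200), settings=fast_solver
        )
        assert classify_outcome(traj, ref_params).classification == "adapted"

    def test_low_state_init_is_switched(self, ref_params, fast_solver):
        prof = make_constant(1.0, 0.0, 80.0)
        low = min(
            (fp for fp in full_fixed_points(ref_params, 1.0) if fp.stable),
            key=lambda fp: fp.state[0],
        )
        traj = simulate_extended(
            ref_params, prof, np.linspace(0, 80, 200), init=low.state, settings=fast_solver
        )
        assert classify_outcome(traj, ref_params).classification == "switched"

    def test_classification_flips_once_with_fold(self, ref_params, fast_solver):
        t_grid = np.linspace(0.0, 200.0, 500)
        labels = []
        for fold in np.arange(1.5, 5.01, 0.25):
            prof = make_steps(1.0, [(20.0, float(fold))], t0=0.0, t_end=200.0)
            traj = simulate_extended(ref_params, prof, t_grid, settings=fast_solver)
            labels.append(classify_outcome(traj, ref_params).classification)
        flips = sum(a != b for a, b in zip(labels, labels[1:]))
        assert flips == 1
        assert labels[0] == "adapted" and labels[-1] == "switched"

    def test_threshold_invariant_to_m0(self, ref_params, fast_solver):
        """Fold-change property: the critical fold does not depend on the
        absolute input level."""
        thresholds = [
            find_switching_threshold(
                ref_params, m0, (1.5, 8.0), settings=fast_solver
            )
            for m0 in (0.5, 1.0, 2.0)
        ]
        assert max(thresholds) / min(thresholds) < 1.005

    def test_small_fold_adapts(self, ref_params, fast_solver):
        prof = make_steps(1.0, [(20.0, 1.05)], t0=0.0, t_end=150.0)
        traj = simulate_extended(
            ref_params, prof, np.linspace(0, 150, 400), settings=fast_solver
        )
        assert classify_outcome(traj, ref_params).classification == "adapted"

    def test_threshold_decreases_with_weaker_Y_repression(self, ref_params, fast_solver):
        """Raising the h-on-Y threshold (Y feels less Her6 repression) makes
        the switch easier to trigger."""
        thresholds = []
        for p0 in (0.45, 0.5, 0.6):
            params = replace(
                ref_params, hill_h_on_Y=HillSpec(ref_params.hill_h_on_Y.n, p0)
            )
            thresholds.append(
                find_switching_threshold(params, 1.0, (1.3, 10.0), settings=fast_solver)
            )
        assert thresholds[0] > thresholds[1] > thresholds[2]

    def test_bracket_must_straddle(self, ref_params, fast_solver):
        with pytest.raises(DomainError):
            find_switching_threshold(ref_params, 1.0, (5.0, 8.0), settings=fast_solver)

    def test_switch_is_irreversible_at_constant_input(self, ref_params, fast_solver):
        """Hysteresis: once switched, holding the input constant never
        restores the high Her6 state."""
        prof = make_steps(
            1.0, [(20.0, 1.5), (60.0, 4.0)], t0=0.0, t_end=400.0
        )
        t_grid = np.linspace(0.0, 400.0, 800)
        traj = simulate_extended(ref_params, prof, t_grid, settings=fast_solver)
        hstar = steady_state_h(ref_params.basic)
        switched_at = np.argmax(traj.h < 0.5 * hstar)
        assert switched_at > 0
        assert np.all(traj.h[switched_at:] < 0.5 * hstar)


class TestFeasibility:
    def test_reference_passes_all_conditions(self, ref_params):
        rep = check_parameter_feasibility(ref_params)
        assert rep.c1_bistable_escape and rep.c2_repressed_at_hstar
        assert rep.c3_finite_threshold
        assert 1.0 < rep.switching_threshold < 100.0

    def test_no_self_activation_fails(self, ref_params):
        rep = check_parameter_feasibility(
            replace(ref_params, beta_Y=0.0), check_threshold=False
        )
        assert not rep.c1_bistable_escape

    def test_hill_coefficient_one_fails(self, ref_params):
        """A non-cooperative self-activation cannot make the scalar Y
        subsystem bistable."""
        p = replace(ref_params, hill_Y_self=HillSpec(1.0, ref_params.hill_Y_self.p0))
        rep = check_parameter_feasibility(p, check_threshold=False)
        assert not rep.c1_bistable_escape

    def test_sampler_returns_feasible_draws(self):
        draws = sample_feasible_parameters(np.random.default_rng(0), 5)
        for p in draws:
            rep = check_parameter_feasibility(p, check_threshold=False)
            assert rep.c1_bistable_escape and rep.c2_repressed_at_hstar


class TestReductionProperty:
    def test_extended_with_inert_Y_matches_basic(self, ref_params):
        """With the Y branch silenced the extended trajectories coincide
        with the basic model on identical inputs."""
        p = replace(ref_params, alpha_Y=1e-12, beta_Y=0.0)
        prof = make_steps(1.0, [(5.0, 3.0)], t0=0.0, t_end=40.0)
        t_grid = np.linspace(0.0, 40.0, 200)
        hstar = steady_state_h(p.basic)
        X0 = steady_state_X(p.basic, 1.0)
        ext = simulate_extended(p, prof, t_grid, init=(hstar, X0, 0.0))
        bas = simulate_basic(p.basic, prof, t_grid, init=(hstar, X0))
        np.testing.assert_allclose(ext.h, bas.h, rtol=1e-6)
        np.testing.assert_allclose(ext.X, bas.X, rtol=1e-6)
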