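"""Basic incoherent feed-forward loop: closed forms, adaptation, symmetry."""

import numpy as np
import pytest

from her6switch.adaptation import (
    AdaptationMetrics,
    BasicModelParameters,
    DomainError,
    SolverSettings,
    adaptation_metrics,
    repression_G,
    rhs_basic,
    simulate_basic,
    steady_state_h,
    steady_state_X,
)
from her6switch.profiles import make_constant, make_linear, make_steps


class TestClosedForms:
    @pytest.mark.parametrize("x, expected", [(1.0, 1.0), (2.0, 0.5), (0.25, 4.0)])
    def test_repression_G(self, x, expected):
        assert repression_G(x) == expected

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_repression_G_pole(self, bad):
        with pytest.raises(DomainError):
            repression_G(bad)

    @pytest.mark.parametrize(
        "params, expected",
        [
            (dict(alpha_h=1, mu_h=1, alpha_X=1, mu_X=1), 1.0),
            (dict(alpha_h=2, mu_h=1, alpha_X=1, mu_X=3), 6.0),
        ],
    )
    def test_steady_state_h(self, params, expected):
        assert steady_state_h(BasicModelParameters(**params)) == expected

    def test_steady_state_X_scaling(self, unit_basic):
        assert steady_state_X(unit_basic, 1.0) == 1.0
        # doubling m halves X*
        assert steady_state_X(unit_basic, 2.0) == 0.5
        p = BasicModelParameters(alpha_h=1, mu_h=1, alpha_X=2, mu_X=4)
        assert steady_state_X(p, 1.0) == 0.5

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(DomainError):
            BasicModelParameters(alpha_h=1, mu_h=0, alpha_X=1, mu_X=1)


class TestRhs:
    def test_direct_substitution(self, unit_basic):
        prof = make_constant(1.0, 0.0, 10.0)
        dh, dX = rhs_basic((1.0, 2.0), 0.0, unit_basic, prof)
        assert dh == pytest.approx(-0.5)  # 1*(1/1)*(1/2) - 1*1

    def test_fixed_point_residual_zero(self, unit_basic):
        m = 3.0
        prof = make_constant(m, 0.0, 10.0)
        state = (steady_state_h(unit_basic), steady_state_X(unit_basic, m))
        np.testing.assert_allclose(rhs_basic(state, 1.0, unit_basic, prof), 0.0, atol=1e-15)

    def test_X_decoupled_from_h(self, unit_basic):
        prof = make_constant(2.0, 0.0, 10.0)
        Xstar = steady_state_X(unit_basic, 2.0)
        for h in (0.1, 1.0, 7.0):
            assert rhs_basic((h, Xstar), 0.0, unit_basic, prof)[1] == pytest.approx(0.0)

    def test_fixed_point_residual_for_random_parameters(self, rng):
        """rhs at the analytic steady state vanishes for arbitrary rates."""
        for _ in range(25):
            vals = rng.uniform(0.1, 5.0, size=5)
            params = BasicModelParameters(*vals[:4])
            m = float(vals[4])
            prof = make_constant(m, 0.0, 1.0)
            state = (steady_state_h(params), steady_state_X(params, m))
            res = rhs_basic(state, 0.0, params, prof)
            assert np.linalg.norm(res) < 1e-12 * max(1.0, steady_state_h(params))


class TestPerfectAdaptation:
    def test_steady_init_stays_at_fixed_point(self, unit_basic):
        prof = make_constant(2.0, 0.0, 40.0)
        traj = simulate_basic(unit_basic, prof, np.linspace(0, 40, 100))
        np.testing.assert_allclose(traj.h, 1.0, rtol=1e-7)

    @pytest.mark.parametrize("m", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("init", [(0.2, 3.0), (4.0, 0.3)])
    def test_convergence_from_arbitrary_states(self, ref_basic, m, init):
        """h converges to the same h* whatever the constant input level."""
        prof = make_constant(m, 0.0, 150.0)
        traj = simulate_basic(ref_basic, prof, np.linspace(0, 150, 200), init=init)
        hstar = steady_state_h(ref_basic)
        assert abs(traj.h[-1] - hstar) / hstar < 1e-6

    def test_step_input_returns_to_h_star(self, unit_basic):
        prof = make_steps(1.0, [(5.0, 2.0)], t0=0.0, t_end=200.0)
        traj = simulate_basic(unit_basic, prof, np.linspace(0, 200, 400))
        assert abs(traj.h[-1] - 1.0) < 1e-6
        # the step produces a real transient first
        assert np.abs(traj.h - 1.0).max() > 0.05

    def test_ramp_transient_exceeds_final_deviation(self, unit_basic):
        prof = make_linear(1.0, 5.0, 0.0, 20.0)
        traj = simulate_basic(unit_basic, prof, np.linspace(0, 120, 400))
        metrics = adaptation_metrics(traj, unit_basic)
        assert metrics.max_relative_deviation > metrics.final_relative_deviation
        assert metrics.final_relative_deviation < 1e-6

    def test_positivity_preserved(self, ref_basic):
        prof = make_steps(1.0, [(5.0, 25.0)], t0=0.0, t_end=60.0)
        traj = simulate_basic(ref_basic, prof, np.linspace(0, 60, 300))
        assert np.all(traj.h > 0) and np.all(traj.X > 0)


class TestFoldChangeSymmetry:
    def _random_profile(self, rng):
        t_edges = np.sort(rng.uniform(2.0, 28.0, size=3))
        bounds = [0.0, *t_edges, 30.0]
        segs = []
        v_prev = rng.uniform(0.3, 3.0)
        for a, b in zip(bounds[:-1], bounds[1:]):
            if rng.random() < 0.5:
                v = rng.uniform(0.3, 3.0)
                segs.append((a, b, "constant", v, v))
                v_prev = v
            else:
                v1 = rng.uniform(0.3, 3.0)
                segs.append((a, b, "linear", v_prev, v1))
                v_prev = v1
        from her6switch.profiles import InputProfile

        return InputProfile(segs)

    def test_rescaled_input_gives_identical_h(self, ref_basic, rng):
        """Exact symmetry: c*m(t) with X0/c reproduces the h trajectory."""
        t_grid = np.linspace(0.0, 30.0, 151)
        for _ in range(5):
            prof = self._random_profile(rng)
            base = simulate_basic(ref_basic, prof, t_grid)
            for c in (0.5, 2.0, 10.0):
                m0 = float(prof(0.0))
                init = (steady_state_h(ref_basic), steady_state_X(ref_basic, m0) / c)
                scaled = simulate_basic(ref_basic, prof.scaled(c), t_grid, init=init)
                np.testing.assert_allclose(scaled.h, base.h, rtol=2e-6)


class TestMetrics:
    def test_constant_input_metrics_are_zero(self, unit_basic):
        prof = make_constant(1.0, 0.0, 20.0)
        traj = simulate_basic(unit_basic, prof, np.linspace(0, 20, 50))
        m = adaptation_metrics(traj, unit_basic)
        assert m.max_relative_deviation < 1e-7
        assert m.final_relative_deviation < 1e-7
        assert m.recovery_time == 0.0

    def test_max_deviation_monotone_in_fold(self, unit_basic):
        devs = []
        for fold in (2.0, 5.0, 10.0):
            prof = make_steps(1.0, [(5.0, fold)], t0=0.0, t_end=100.0)
            traj = simulate_basic(unit_basic, prof, np.linspace(0, 100, 300))
            devs.append(adaptation_metrics(traj, unit_basic).max_relative_deviation)
        assert devs[0] < devs[1] < devs[2]

    def test_recovery_speeds_up_with_mu_X(self):
        """Adaptation speed is set by the indirect (X) branch turnover."""
        times = []
        for mu_X in (0.2, 0.5, 1.5):
            params = BasicModelParameters(alpha_h=1.0, mu_h=1.0, alpha_X=mu_X, mu_X=mu_X)
            prof = make_steps(1.0, [(5.0, 3.0)], t0=0.0, t_end=150.0)
            traj = simulate_basic(params, prof, np.linspace(0, 150, 1000))
            times.append(adaptation_metrics(traj, params).recovery_time)
        assert times[0] > times[1] > times[2]
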