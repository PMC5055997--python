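"""Integration, equilibrium solving, the steady-state identity, stability."""

import math

import numpy as np
import pytest

from sosa_spsa import (
    ModelParameters,
    PopulationState,
    assess_stability,
    eq2_residual,
    equilibrate,
    find_equilibrium,
    modified_rhs,
    multistart_equilibria,
    simulate,
)
from sosa_spsa.dynamics import (
    DegenerateDenominatorError,
    EquilibriumNotFound,
    reduced_jacobian,
)
from sosa_spsa.model import _reduced_rhs

from conftest import random_valid_params


class TestSimulate:
    def test_reference_narrative(self, fhs_config, fhs_trajectory):
        """Optimists rise, pessimists fall; susceptibles rise then fall."""
        traj = fhs_trajectory
        assert traj.O[1] > traj.O[0] and traj.P[1] < traj.P[0]
        i_peak = int(np.argmax(traj.S))
        assert 0 < i_peak < len(traj) - 1
        assert traj.S[-1] < traj.S[i_peak]

    def test_contagion_free_initial_state_is_constant(self, fhs_config):
        params = fhs_config.params.replace(alpha_O=0.0, alpha_P=0.0)
        N = fhs_config.N
        traj = simulate(params, PopulationState(N, 0.0, 0.0), N, t_end=50.0)
        assert np.allclose(traj.S, N, rtol=0, atol=1e-9 * N)
        assert np.all(traj.O == 0.0) and np.all(traj.P == 0.0)

    def test_terminal_state_self_convergence(self, fhs_config):
        """Tightening the integrator tolerance twice moves the terminal
        state by far less than the acceptance scale."""
        c = fhs_config
        finals = [
            simulate(c.params, c.initial, c.N, t_end=500.0, rtol=rtol).final_state.as_array()
            for rtol in (4e-10, 2e-10, 1e-10)
        ]
        assert np.abs(finals[0] - finals[2]).max() < 1e-6 * c.N
        assert np.abs(finals[1] - finals[2]).max() < 1e-6 * c.N

    def test_rejects_bad_inputs(self, fhs_config):
        with pytest.raises(ValueError):
            simulate(fhs_config.params, fhs_config.initial, fhs_config.N, t_end=-1.0)
        with pytest.raises(ValueError):
            simulate(fhs_config.params, PopulationState(1, 1, 1), fhs_config.N)


class TestFindEquilibrium:
    def test_agrees_with_long_run_integration(self, fhs_config, fhs_trajectory, fhs_equilibrium):
        c = fhs_config
        terminal = fhs_trajectory.final_state.fractions(c.N).as_array()
        solved = fhs_equilibrium.state.fractions(c.N).as_array()
        assert np.abs(terminal - solved).max() < 1e-6

    def test_contagion_free_fixed_point(self, fhs_config):
        params = fhs_config.params.replace(alpha_O=0.0, alpha_P=0.0)
        N = fhs_config.N
        eq = find_equilibrium(params, PopulationState(N, 0.0, 0.0), N)
        assert eq.state.as_array() == pytest.approx([N, 0.0, 0.0], abs=1e-9 * N)

    def test_steady_state_identity_holds(self, fhs_config, fhs_equilibrium):
        """Both channel expressions of the identity equal S at the root."""
        c = fhs_config
        p, s = c.params, fhs_equilibrium.state
        lhs = (p.g_P * s.P + s.O * s.P * (p.m1 + p.m2 - p.l2) / c.N) / (
            p.alpha_P + p.beta_P * s.P / c.N
        )
        rhs = (p.g_O * s.O + s.O * s.P * (p.l1 + p.l2 - p.m2) / c.N) / (
            p.alpha_O + p.beta_O * s.O / c.N
        )
        assert lhs == pytest.approx(s.S, abs=1e-8 * c.N)
        assert rhs == pytest.approx(s.S, abs=1e-8 * c.N)
        assert fhs_equilibrium.residual_eq2 <= 1e-8 * c.N

    def test_matches_integration_on_random_parameter_sets(self, fhs_config):
        """Algebraic root and long-run integration agree whenever both
        converge, across 50 random valid parameter draws."""
        rng = np.random.default_rng(2024)
        initial, N = fhs_config.initial, fhs_config.N
        compared = 0
        for _ in range(50):
            params = random_valid_params(rng)
            try:
                integrated, _ = equilibrate(params, initial, N)
                solved = find_equilibrium(params, initial, N)
            except (EquilibriumNotFound, RuntimeError):
                continue
            diff = np.abs(integrated.as_array() - solved.state.as_array()).max()
            assert diff < 1e-5 * N
            compared += 1
        assert compared >= 40

    def test_single_equilibrium_from_multistart(self, fhs_config):
        roots = multistart_equilibria(fhs_config.params, fhs_config.N)
        assert len(roots) == 1


class TestEq2Residual:
    def test_positive_away_from_equilibrium(self, fhs_config):
        r = eq2_residual(fhs_config.initial, fhs_config.params, fhs_config.N)
        assert r > 0.1

    def test_grows_with_perturbation(self, fhs_config, fhs_equilibrium):
        s, c = fhs_equilibrium.state, fhs_config
        residuals = [
            eq2_residual(PopulationState(s.S - d, s.O + d, s.P), c.params, c.N)
            for d in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert all(b > a for a, b in zip(residuals, residuals[1:]))

    def test_degenerate_denominator_raises(self, fhs_config):
        params = fhs_config.params.replace(alpha_P=0.0)
        state = PopulationState(fhs_config.N, 0.0, 0.0)  # P = 0 kills den_P
        with pytest.raises(DegenerateDenominatorError):
            eq2_residual(state, params, fhs_config.N)


class TestStability:
    def test_reference_equilibrium_is_stable(self, fhs_config, fhs_equilibrium):
        eq = assess_stability(fhs_equilibrium, fhs_config.params, fhs_config.N)
        assert eq.stable is True
        assert all(ev.real < 0 for ev in eq.eigenvalues)

    def test_decoupled_linear_decay_eigenvalues(self):
        """With no transmission and no spontaneity the reduced system is
        linear: eigenvalues are exactly -g_O and -g_P."""
        params = ModelParameters(0.0, 0.0, 0.12, 0.0, 0.0, 0.3)
        N = 1000.0
        eq = find_equilibrium(params, PopulationState(N, 0.0, 0.0), N)
        eq = assess_stability(eq, params, N)
        got = sorted(ev.real for ev in eq.eigenvalues)
        assert got == pytest.approx([-0.3, -0.12], rel=1e-6)
        assert eq.stable

    def test_finite_difference_jacobian_matches_analytic(self, fhs_config):
        """Central differences reproduce the hand-derived Jacobian of the
        reduced (O, P) system on random interior states."""
        p, N = fhs_config.params, fhs_config.N
        c = 1.0 / N
        rng = np.random.default_rng(7)
        for _ in range(20):
            o, pp = rng.dirichlet([1, 1, 1])[:2]
            O, P = o * N, pp * N
            J = reduced_jacobian(PopulationState(N - O - P, O, P), p, N)
            a = np.array([
                [
                    -p.g_O - p.alpha_O + c * p.beta_O * (N - 2 * O - P)
                    - c * (p.l1 + p.l2 - p.m2) * P,
                    -p.alpha_O - c * p.beta_O * O - c * (p.l1 + p.l2 - p.m2) * O,
                ],
                [
                    -p.alpha_P - c * p.beta_P * P - c * (p.m1 + p.m2 - p.l2) * P,
                    -p.g_P - p.alpha_P + c * p.beta_P * (N - O - 2 * P)
                    - c * (p.m1 + p.m2 - p.l2) * O,
                ],
            ])
            assert np.abs(J - a).max() < 1e-5


def test_reduced_rhs_consistency(fhs_config):
    """The solver-facing reduced form matches the public rhs."""
    c = fhs_config
    d = modified_rhs(c.initial, c.params, c.N)
    dO, dP = _reduced_rhs(c.initial.O, c.initial.P, c.initial.S, c.params, c.N)
    assert (dO, dP) == (d.dO_dt, d.dP_dt)
    assert math.isclose(d.dS_dt, -(dO + dP), rel_tol=0, abs_tol=0)
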