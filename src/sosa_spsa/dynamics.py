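"""Trajectory integration, equilibria and stability for the modified model.

Two independent routes to the steady state are provided: long-run
integration (:func:`simulate` / :func:`equilibrate`) and algebraic root
finding on the reduced two-dimensional (O, P) system with S = N - O - P
(:func:`find_equilibrium`).  The reduced formulation enforces population
conservation exactly by construction.

At a steady state the model satisfies a closed-form identity relating the
two sentiment channels: both

    (g_P*P + c*O*P*(m1+m2-l2)) / (alpha_P + c*beta_P*P)   and
    (g_O*O + c*O*P*(l1+l2-m2)) / (alpha_O + c*beta_O*O)

equal S.  :func:`eq2_residual` measures the mismatch between the two sides
and is used as an independent equilibrium check.

Stability is assessed numerically: :func:`assess_stability` builds the 2x2
Jacobian of the reduced system by central finite differences and inspects
its eigenvalues.  No analytic global stability result is attempted; the
multi-start helper only probes for coexisting equilibria.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import (
    InvalidPopulationError,
    ModelParameters,
    PopulationState,
    _reduced_rhs,
    modified_rhs,
    validate_parameters,
)

__all__ = [
    "Trajectory",
    "EquilibriumResult",
    "SolverFailure",
    "EquilibriumNotFound",
    "DegenerateDenominatorError",
    "simulate",
    "equilibrate",
    "find_equilibrium",
    "eq2_residual",
    "assess_stability",
    "multistart_equilibria",
]

#: default integrator tolerances: tight enough that conservation checks
#: at 1e-8 relative are meaningful
DEFAULT_RTOL = 1e-10
DEFAULT_ATOL_PER_N = 1e-12

#: tolerated negative overshoot, relative to N
NEGATIVITY_BAND = 1e-9


class SolverFailure(RuntimeError):
    """Integration failed (e.g. step-size collapse); carries the time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class EquilibriumNotFound(RuntimeError):
    """Root finding did not converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: PopulationState | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


class DegenerateDenominatorError(ZeroDivisionError):
    """A denominator of the equilibrium identity is zero."""


@dataclass(frozen=True)
class Trajectory:
    """Time grid plus aligned states from integrating one parameter set."""

    times: np.ndarray          # strictly increasing, shape (n,)
    S: np.ndarray              # shape (n,)
    O: np.ndarray
    P: np.ndarray
    params: ModelParameters
    N: float

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, i: int) -> PopulationState:
        return PopulationState(float(self.S[i]), float(self.O[i]), float(self.P[i]))

    @property
    def final_state(self) -> PopulationState:
        return self.state_at(-1)

    def to_frame(self, fractions: bool = False) -> pd.DataFrame:
        scale = self.N if fractions else 1.0
        return pd.DataFrame(
            {"t": self.times, "S": self.S / scale, "O": self.O / scale, "P": self.P / scale}
        )

    def to_csv(self, path: str | Path, fractions: bool = False) -> None:
        """Write `t,S,O,P` rows at full double precision."""
        self.to_frame(fractions=fractions).to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class EquilibriumResult:
    """A steady state with its residuals and (optionally) its stability."""

    state: PopulationState
    residual_rhs: float            # max |derivative component| at the state
    residual_eq2: float            # mismatch of the equilibrium identity
    eigenvalues: tuple[complex, ...] | None = None   # reduced 2-D Jacobian
    stable: bool | None = None     # all eigenvalue real parts < 0

    def to_dict(self) -> dict:
        d = {
            "S": self.state.S,
            "O": self.state.O,
            "P": self.state.P,
            "residual_rhs": self.residual_rhs,
            "residual_eq2": self.residual_eq2,
        }
        if self.eigenvalues is not None:
            d["eigenvalues_re"] = [ev.real for ev in self.eigenvalues]
            d["eigenvalues_im"] = [ev.imag for ev in self.eigenvalues]
            d["stable"] = self.stable
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _check_inputs(params: ModelParameters, initial: PopulationState, N: float) -> None:
    validate_parameters(params).raise_if_invalid()
    if N <= 0:
        raise InvalidPopulationError(f"total population N must be > 0, got {N}")
    if abs(initial.total - N) > 1e-6 * N:
        raise InvalidPopulationError(
            f"initial state sums to {initial.total}, expected N={N}"
        )


def simulate(
    params: ModelParameters,
    initial: PopulationState,
    N: float | None = None,
    t_end: float = 200.0,
    n_points: int = 400,
    rtol: float = DEFAULT_RTOL,
    atol: float | None = None,
) -> Trajectory:
    """Integrate the modified model on [0, t_end].

    Uses an adaptive stiff-capable integrator (LSODA).  The returned
    trajectory is checked for conservation (S+O+P = N to 1e-8 relative)
    and for material negativity; either violation raises
    :class:`SolverFailure` rather than being clipped.
    """
    if N is None:
        N = initial.total
    _check_inputs(params, initial, N)
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if atol is None:
        atol = DEFAULT_ATOL_PER_N * N

    def f(t: float, y: np.ndarray) -> list[float]:
        dO, dP = _reduced_rhs(y[1], y[2], y[0], params, N)
        return [-(dO + dP), dO, dP]

    times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        f, (0.0, t_end), initial.as_array(), t_eval=times,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else 0.0
        raise SolverFailure(f"integration failed at t={t_fail}: {sol.message}", t_fail)

    S, O, P = sol.y
    total_err = np.max(np.abs(S + O + P - N))
    if total_err > 1e-8 * N:
        raise SolverFailure(f"conservation violated: max |S+O+P-N| = {total_err:g}")
    worst = min(S.min(), O.min(), P.min())
    if worst < -NEGATIVITY_BAND * N:
        raise SolverFailure(f"material negative compartment: min value {worst:g}")
    return Trajectory(sol.t, S, O, P, params, N)


def equilibrate(
    params: ModelParameters,
    initial: PopulationState,
    N: float | None = None,
    tol: float = 1e-10,
    t_end: float = 2000.0,
    max_doublings: int = 1,
) -> tuple[PopulationState, float]:
    """Find the steady state by long-run integration.

    Integrates to ``t_end`` and accepts the terminal state when the largest
    derivative component is below ``tol * N``; otherwise doubles ``t_end``
    up to ``max_doublings`` times.  Returns the state and the horizon used.
    """
    if N is None:
        N = initial.total
    horizon = t_end
    for _ in range(max_doublings + 1):
        traj = simulate(params, initial, N, t_end=horizon, n_points=200)
        final = traj.final_state
        if modified_rhs(final, params, N).max_abs < tol * N:
            return final, horizon
        horizon *= 2.0
    raise SolverFailure(
        f"no steady state by t={horizon / 2:g}: residual "
        f"{modified_rhs(final, params, N).max_abs:g} > {tol * N:g}"
    )


def find_equilibrium(
    params: ModelParameters,
    guess: PopulationState,
    N: float | None = None,
    tol: float | None = None,
) -> EquilibriumResult:
    """Solve for a steady state by root finding in the reduced (O, P) plane.

    S = N - O - P is eliminated, so conservation holds by construction.
    Powell's hybrid method is started from ``guess``.  The converged state
    must have residual_rhs <= ``tol`` (default ``1e-10 * N``) and no
    component below the negativity band; otherwise
    :class:`EquilibriumNotFound` is raised carrying the last iterate.
    """
    if N is None:
        N = guess.total
    _check_inputs(params, guess, N)
    if tol is None:
        tol = 1e-10 * N

    def f(x: np.ndarray) -> list[float]:
        O, P = x
        return list(_reduced_rhs(O, P, N - O - P, params, N))

    sol = root(f, np.array([guess.O, guess.P]), method="hybr", tol=1e-14)
    O, P = sol.x
    state = PopulationState(N - O - P, float(O), float(P))
    residual = modified_rhs(state, params, N).max_abs
    if residual > tol:
        raise EquilibriumNotFound(
            f"root finder residual {residual:g} exceeds tol {tol:g}: {sol.message}",
            last_iterate=state,
        )
    if min(state.S, state.O, state.P) < -NEGATIVITY_BAND * N:
        raise EquilibriumNotFound(
            f"converged to a negative compartment: {state}", last_iterate=state
        )
    try:
        r_eq2 = eq2_residual(state, params, N)
    except DegenerateDenominatorError:
        # identity undefined when alpha + c*beta*X = 0 (its side condition)
        r_eq2 = float("nan")
    return EquilibriumResult(state, residual, r_eq2)


def eq2_residual(state: PopulationState, params: ModelParameters, N: float) -> float:
    """Mismatch of the steady-state identity between the two channels.

    Both sides equal S at an equilibrium of the O/P subsystem; away from
    equilibrium the absolute difference is strictly positive.  A zero
    denominator (``alpha + c*beta*X = 0``) raises
    :class:`DegenerateDenominatorError`.
    """
    c = params.contact_rate(N)
    p = params
    den_P = p.alpha_P + c * p.beta_P * state.P
    den_O = p.alpha_O + c * p.beta_O * state.O
    if den_P == 0.0 or den_O == 0.0:
        raise DegenerateDenominatorError(
            f"degenerate equilibrium identity: denominators ({den_O}, {den_P})"
        )
    OP = state.O * state.P
    lhs = (p.g_P * state.P + c * OP * (p.m1 + p.m2 - p.l2)) / den_P
    rhs = (p.g_O * state.O + c * OP * (p.l1 + p.l2 - p.m2)) / den_O
    return abs(lhs - rhs)


def reduced_jacobian(
    state: PopulationState,
    params: ModelParameters,
    N: float,
    h_rel: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference Jacobian of the reduced (O, P) system.

    Step size is ``h_rel * N`` in each coordinate; S = N - O - P moves in
    compensation, so the differencing stays on the conservation plane.
    """
    h = h_rel * N

    def f(O: float, P: float) -> np.ndarray:
        return np.array(_reduced_rhs(O, P, N - O - P, params, N))

    O, P = state.O, state.P
    J = np.empty((2, 2))
    J[:, 0] = (f(O + h, P) - f(O - h, P)) / (2 * h)
    J[:, 1] = (f(O, P + h) - f(O, P - h)) / (2 * h)
    return J


def assess_stability(
    eq: EquilibriumResult, params: ModelParameters, N: float
) -> EquilibriumResult:
    """Populate eigenvalues and the stability flag of an equilibrium.

    The equilibrium is (locally, numerically) stable iff every eigenvalue
    of the reduced Jacobian has negative real part.
    """
    J = reduced_jacobian(eq.state, params, N)
    eigenvalues = tuple(complex(ev) for ev in np.linalg.eigvals(J))
    stable = all(ev.real < 0 for ev in eigenvalues)
    return replace(eq, eigenvalues=eigenvalues, stable=stable)


def multistart_equilibria(
    params: ModelParameters,
    N: float,
    tol: float | None = None,
) -> list[EquilibriumResult]:
    """Probe for coexisting equilibria from 16 simplex-grid starting points.

    Guesses are the barycentric grid of resolution 4 on the S/O/P simplex
    plus the centroid.  Roots closer than ``1e-6 * N`` (in O and P) are
    deduplicated.  Exploratory only: finding a single root is not a proof
    of a globally attracting equilibrium.
    """
    guesses = [
        PopulationState(N * (4 - i - j) / 4, N * i / 4, N * j / 4)
        for i in range(5)
        for j in range(5 - i)
    ]
    guesses.append(PopulationState(N / 3, N / 3, N / 3))
    found: list[EquilibriumResult] = []
    for g in guesses:
        try:
            eq = find_equilibrium(params, g, N, tol=tol)
        except EquilibriumNotFound:
            continue
        if not any(
            abs(eq.state.O - e.state.O) < 1e-6 * N and abs(eq.state.P - e.state.P) < 1e-6 * N
            for e in found
        ):
            found.append(eq)
    return found
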