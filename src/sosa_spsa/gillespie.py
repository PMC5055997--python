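"""Exact event-driven stochastic simulation of the modified model.

The ten elementary transitions of the contagion scheme are simulated on an
integer population with the Gillespie direct method: propensities are the
ten right-hand-side terms evaluated at the current integer state (frequency
scaling), waiting times are exponential in the total propensity, and each
event moves exactly one individual, so conservation is exact and integer.

This serves as an independent correctness oracle for the deterministic
mean-field system: ensemble means converge to the ODE trajectory as N
grows, with relative fluctuations shrinking like 1/sqrt(N).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    InvalidPopulationError,
    ModelParameters,
    PopulationState,
    validate_parameters,
)

__all__ = [
    "EVENT_KINDS",
    "EventSchedule",
    "EnsembleResult",
    "gillespie_run",
    "ensemble_mean",
    "scale_initial_state",
]

#: the ten elementary transitions, in the order propensities are evaluated
EVENT_KINDS = (
    "S->O spontaneous",
    "S->O contact",
    "O->S recovery",
    "S->P spontaneous",
    "S->P contact",
    "P->S recovery",
    "O->S interaction",   # optimist meets pessimist, rate l1
    "O->P interaction",   # optimist meets pessimist, rate l2
    "P->S interaction",   # pessimist meets optimist, rate m1
    "P->O interaction",   # pessimist meets optimist, rate m2
)

# per-event change to (S, O, P)
_DELTAS = (
    (-1, 1, 0), (-1, 1, 0), (1, -1, 0),
    (-1, 0, 1), (-1, 0, 1), (1, 0, -1),
    (1, -1, 0), (0, -1, 1), (1, 0, -1), (0, 1, -1),
)

_BLOCK = 1 << 14  # uniform variates drawn in blocks for speed


@dataclass(frozen=True)
class EventSchedule:
    """One stochastic realization: every event with the state after it."""

    seed: int
    t0_state: tuple[int, int, int]          # (S, O, P) at t = 0
    times: np.ndarray                       # nondecreasing event times
    kinds: np.ndarray                       # indices into EVENT_KINDS
    states: np.ndarray                      # (n_events, 3) ints, state after
    t_end: float
    absorbed: bool                          # all propensities hit zero

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, t: float) -> tuple[int, int, int]:
        """The integer state in force at time ``t`` (right-continuous)."""
        i = int(np.searchsorted(self.times, t, side="right"))
        return self.t0_state if i == 0 else tuple(int(x) for x in self.states[i - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "event": [EVENT_KINDS[k] for k in self.kinds],
                "S": self.states[:, 0],
                "O": self.states[:, 1],
                "P": self.states[:, 2],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class EnsembleResult:
    """Per-time-point ensemble mean and standard error of each compartment."""

    t_grid: np.ndarray
    mean: np.ndarray      # (len(t_grid), 3), columns S, O, P
    se: np.ndarray        # standard error of the mean, same shape
    n_runs: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t_grid,
                "mean_S": self.mean[:, 0], "se_S": self.se[:, 0],
                "mean_O": self.mean[:, 1], "se_O": self.se[:, 1],
                "mean_P": self.mean[:, 2], "se_P": self.se[:, 2],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _check_integer_state(initial: PopulationState, N: float) -> tuple[int, int, int]:
    s, o, p = initial.S, initial.O, initial.P
    if not all(float(x).is_integer() and x >= 0 for x in (s, o, p)):
        raise InvalidPopulationError(f"stochastic runs need nonnegative integer counts, got {initial}")
    if int(s + o + p) != int(N) or N <= 0:
        raise InvalidPopulationError(f"initial state sums to {s + o + p}, expected N={N}")
    return int(s), int(o), int(p)


def _propensities(S: int, O: int, P: int, p: ModelParameters, c: float) -> list[float]:
    OP = c * O * P
    return [
        p.alpha_O * S,
        c * p.beta_O * O * S,
        p.g_O * O,
        p.alpha_P * S,
        c * p.beta_P * P * S,
        p.g_P * P,
        p.l1 * OP,
        p.l2 * OP,
        p.m1 * OP,
        p.m2 * OP,
    ]


class _Uniforms:
    """Blocked stream of uniform(0,1) variates from a seeded Generator."""

    def __init__(self, seed: int):
        self._rng = np.random.default_rng(seed)
        self._buf = self._rng.random(_BLOCK)
        self._i = 0

    def next(self) -> float:
        if self._i == _BLOCK:
            self._buf = self._rng.random(_BLOCK)
            self._i = 0
        u = self._buf[self._i]
        self._i += 1
        return u


def gillespie_run(
    params: ModelParameters,
    initial: PopulationState,
    N: float,
    t_end: float,
    seed: int,
) -> EventSchedule:
    """One exact stochastic realization on [0, t_end], direct method.

    Event selection inverts the cumulative propensity; on an (almost
    surely impossible) tie of cumulative bounds the lower-indexed event
    fires.  If every propensity reaches zero the run is absorbed and ends
    early.  A fixed seed reproduces the event sequence bit for bit.
    """
    validate_parameters(params).raise_if_invalid()
    S, O, P = _check_integer_state(initial, N)
    c = params.contact_rate(N)
    uni = _Uniforms(seed)

    times: list[float] = []
    kinds: list[int] = []
    states: list[tuple[int, int, int]] = []
    t = 0.0
    absorbed = False
    while True:
        props = _propensities(S, O, P, params, c)
        total = sum(props)
        if total <= 0.0:
            absorbed = True
            break
        t += -np.log(1.0 - uni.next()) / total
        if t > t_end:
            break
        target = uni.next() * total
        acc = 0.0
        for k in range(10):
            acc += props[k]
            if target < acc or k == 9:
                break
        dS, dO, dP = _DELTAS[k]
        S += dS
        O += dO
        P += dP
        times.append(t)
        kinds.append(k)
        states.append((S, O, P))

    return EventSchedule(
        seed=seed,
        t0_state=_check_integer_state(initial, N),
        times=np.array(times),
        kinds=np.array(kinds, dtype=np.int8),
        states=np.array(states, dtype=np.int64).reshape(len(states), 3),
        t_end=t_end,
        absorbed=absorbed,
    )


def _run_on_grid(
    params: ModelParameters,
    S: int, O: int, P: int,
    c: float,
    t_grid: np.ndarray,
    seed: int,
) -> np.ndarray:
    """One realization sampled on ``t_grid`` without storing events."""
    uni = _Uniforms(seed)
    out = np.empty((len(t_grid), 3), dtype=np.int64)
    t = 0.0
    i = 0
    n_grid = len(t_grid)
    while i < n_grid:
        props = _propensities(S, O, P, params, c)
        total = sum(props)
        if total <= 0.0:
            t_next = np.inf
        else:
            t_next = t - np.log(1.0 - uni.next()) / total
        while i < n_grid and t_grid[i] < t_next:
            out[i] = (S, O, P)
            i += 1
        if i == n_grid or not np.isfinite(t_next):
            break
        t = t_next
        target = uni.next() * total
        acc = 0.0
        for k in range(10):
            acc += props[k]
            if target < acc or k == 9:
                break
        dS, dO, dP = _DELTAS[k]
        S += dS
        O += dO
        P += dP
    # absorbed before the grid ran out: state is constant from here on
    while i < n_grid:
        out[i] = (S, O, P)
        i += 1
    return out


def ensemble_mean(
    params: ModelParameters,
    initial: PopulationState,
    N: float,
    t_grid: np.ndarray,
    n_runs: int,
    seed: int,
) -> EnsembleResult:
    """Ensemble mean and standard error over independent realizations.

    Run ``i`` uses sub-seed ``seed + i``, so any run is individually
    reproducible with :func:`gillespie_run`.  Requires ``n_runs >= 2`` for
    the standard error to be defined.
    """
    if n_runs < 2:
        raise ValueError(f"n_runs must be >= 2, got {n_runs}")
    validate_parameters(params).raise_if_invalid()
    S, O, P = _check_integer_state(initial, N)
    t_grid = np.asarray(t_grid, dtype=float)
    c = params.contact_rate(N)

    samples = np.empty((n_runs, len(t_grid), 3))
    for i in range(n_runs):
        samples[i] = _run_on_grid(params, S, O, P, c, t_grid, seed + i)
    mean = samples.mean(axis=0)
    se = samples.std(axis=0, ddof=1) / np.sqrt(n_runs)
    return EnsembleResult(t_grid, mean, se, n_runs, seed)


def scale_initial_state(state: PopulationState, new_N: int) -> PopulationState:
    """Rescale a state to a new total using largest-remainder rounding.

    Counts are scaled proportionally and floored; the leftover individuals
    are assigned to the compartments with the largest fractional parts, so
    the result is integer and sums exactly to ``new_N``.
    """
    if new_N <= 0:
        raise InvalidPopulationError(f"new_N must be > 0, got {new_N}")
    exact = state.as_array() * (new_N / state.total)
    floors = np.floor(exact).astype(np.int64)
    shortfall = int(new_N - floors.sum())
    order = np.argsort(-(exact - floors))  # largest remainders first
    for j in range(shortfall):
        floors[order[j]] += 1
    return PopulationState(*(float(x) for x in floors))
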