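"""Parameter sweeps over equilibrium composition.

Each sweep solves for the steady state at every grid point with the
algebraic root finder, warm-starting each point from the previous point's
equilibrium for continuity (the first point starts from the base
parameters' own equilibrium).  Results are long-format tables of the
equilibrium composition as fractions of N.

The sweeps cover the three questions the model is typically interrogated
with: how the pessimist recovery rate g_P regulates the equilibrium number
of pessimists (it decreases it, with diminishing returns); how the fate
split l1/l2 of an optimist meeting a pessimist shifts the balance (faster
conversion to pessimism, l2 > l1, inflates the pessimist pool); and how
the spontaneous pessimism rate alpha_P interacts with the (l2, m2) pair
(more pessimists, saturating at high alpha_P).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import EquilibriumNotFound, find_equilibrium
from .model import ModelParameters, PopulationState, validate_parameters

__all__ = [
    "SweepResult",
    "DEFAULT_GP_GRID",
    "DEFAULT_L2_GRID",
    "DEFAULT_ALPHA_P_GRID",
    "DEFAULT_LM_PAIRS",
    "sweep_g_P",
    "sweep_l2_vs_l1",
    "sweep_alpha_P_by_lm",
    "plot_sweep",
]

# default grids bracket the reference fixture values (g_P = 0.13,
# l1 = 0.13, l2 = 0.009, m2 = 0.07, alpha_P = 0.04)
DEFAULT_GP_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 10))
DEFAULT_L2_GRID = tuple(np.round(np.arange(0.0, 0.301, 0.03), 10))
DEFAULT_ALPHA_P_GRID = (0.01, 0.04, 0.07, 0.1)
DEFAULT_LM_PAIRS = ((0.009, 0.07), (0.07, 0.009))


@dataclass(frozen=True)
class SweepResult:
    """Equilibrium composition along a parameter grid.

    ``grid`` rows align with ``frac_S``/``frac_O``/``frac_P`` and
    ``converged``; each grid row is a dict of the varied parameter values.
    Non-converged points carry NaN fractions and are excluded from any
    monotonicity reasoning.
    """

    swept: tuple[str, ...]
    grid: tuple[dict, ...]
    frac_S: np.ndarray
    frac_O: np.ndarray
    frac_P: np.ndarray
    converged: tuple[bool, ...]
    skipped: tuple[dict, ...] = field(default_factory=tuple)  # invalid combos

    def __len__(self) -> int:
        return len(self.grid)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, point in enumerate(self.grid):
            for name, value in point.items():
                rows.append(
                    {
                        "param_name": name,
                        "param_value": value,
                        "frac_S": self.frac_S[i],
                        "frac_O": self.frac_O[i],
                        "frac_P": self.frac_P[i],
                        "converged": self.converged[i],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def pessimist_fractions(self, **fixed: float) -> list[tuple[dict, float]]:
        """Converged (grid point, frac_P) pairs matching the fixed values."""
        out = []
        for i, point in enumerate(self.grid):
            if self.converged[i] and all(point.get(k) == v for k, v in fixed.items()):
                out.append((point, float(self.frac_P[i])))
        return out


def _solve_grid(
    base: ModelParameters,
    N: float,
    points: Sequence[dict],
    warm: PopulationState,
    tol: float | None = None,
) -> SweepResult:
    """Warm-started equilibrium solve at each parameter combination."""
    fS, fO, fP, conv = [], [], [], []
    guess = warm
    for point in points:
        params = base.replace(**point)
        try:
            eq = find_equilibrium(params, guess, N, tol=tol)
            st = eq.state
            fS.append(st.S / N)
            fO.append(st.O / N)
            fP.append(st.P / N)
            conv.append(True)
            guess = st
        except EquilibriumNotFound:
            fS.append(np.nan)
            fO.append(np.nan)
            fP.append(np.nan)
            conv.append(False)
    swept = tuple(sorted({k for p in points for k in p}))
    return SweepResult(
        swept, tuple(points), np.array(fS), np.array(fO), np.array(fP), tuple(conv)
    )


def _base_equilibrium(base: ModelParameters, N: float) -> PopulationState:
    validate_parameters(base).raise_if_invalid()
    guess = PopulationState(N / 3, N / 3, N / 3)
    return find_equilibrium(base, guess, N).state


def sweep_g_P(
    base: ModelParameters,
    N: float,
    gP_grid: Sequence[float] = DEFAULT_GP_GRID,
    tol: float | None = None,
) -> SweepResult:
    """Equilibrium composition as the pessimist recovery rate varies.

    The equilibrium pessimist count decreases strictly along an increasing
    grid, with successive decrements shrinking (the curve flattens as
    recovery speeds up).
    """
    if not all(g > 0 for g in gP_grid):
        raise ValueError("gP_grid must be positive")
    if any(b >= a for a, b in zip(gP_grid[1:], gP_grid)):
        raise ValueError("gP_grid must be strictly increasing")
    points = [{"g_P": float(g)} for g in gP_grid]
    return _solve_grid(base, N, points, _base_equilibrium(base, N), tol)


def sweep_l2_vs_l1(
    base: ModelParameters,
    N: float,
    l2_grid: Sequence[float] = DEFAULT_L2_GRID,
    l1_grid: Sequence[float] | None = None,
    tol: float | None = None,
) -> SweepResult:
    """Equilibrium composition over the optimist-fate split (l1, l2).

    Pairs violating ``l1 + l2 <= 1`` are skipped and reported in
    ``skipped``.  At fixed l1 the pessimist fraction increases with l2;
    the l2 > l1 region carries more pessimists than its mirror image.
    """
    if l1_grid is None:
        l1_grid = (base.l1,)
    points, skipped = [], []
    for l1 in l1_grid:
        for l2 in l2_grid:
            combo = {"l1": float(l1), "l2": float(l2)}
            if l1 + l2 <= 1 and l1 >= 0 and l2 >= 0:
                points.append(combo)
            else:
                skipped.append(combo)
    result = _solve_grid(base, N, points, _base_equilibrium(base, N), tol)
    return SweepResult(
        result.swept, result.grid, result.frac_S, result.frac_O, result.frac_P,
        result.converged, tuple(skipped),
    )


def sweep_alpha_P_by_lm(
    base: ModelParameters,
    N: float,
    alphaP_grid: Sequence[float] = DEFAULT_ALPHA_P_GRID,
    lm_pairs: Sequence[tuple[float, float]] = DEFAULT_LM_PAIRS,
    tol: float | None = None,
) -> SweepResult:
    """Spontaneous pessimism rate crossed with (l2, m2) fate pairs.

    For each (l2, m2) pair the pessimist fraction is nondecreasing in
    alpha_P and saturates: increments between successive large alpha_P
    values are smaller than between successive small ones.  At fixed
    alpha_P, more l2 means more pessimists and more m2 means fewer.
    """
    points, skipped = [], []
    for l2, m2 in lm_pairs:
        for a in alphaP_grid:
            combo = {"alpha_P": float(a), "l2": float(l2), "m2": float(m2)}
            test = base.replace(**combo)
            if validate_parameters(test).ok:
                points.append(combo)
            else:
                skipped.append(combo)
    result = _solve_grid(base, N, points, _base_equilibrium(base, N), tol)
    return SweepResult(
        result.swept, result.grid, result.frac_S, result.frac_O, result.frac_P,
        result.converged, tuple(skipped),
    )


def plot_sweep(result: SweepResult, x: str, path: str | Path) -> None:
    """Write a static line plot of the pessimist fraction against ``x``.

    Grid points are grouped by the values of the other swept parameters;
    one line per group.  Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    others = [s for s in result.swept if s != x]
    groups: dict[tuple, list[tuple[float, float]]] = {}
    for i, point in enumerate(result.grid):
        if not result.converged[i]:
            continue
        key = tuple((o, point[o]) for o in others if o in point)
        groups.setdefault(key, []).append((point[x], float(result.frac_P[i])))

    fig, ax = plt.subplots(figsize=(6, 4))
    for key, pairs in groups.items():
        pairs.sort()
        xs, ys = zip(*pairs)
        label = ", ".join(f"{k}={v:g}" for k, v in key) or None
        ax.plot(xs, ys, marker="o", label=label)
    ax.set_xlabel(x)
    ax.set_ylabel("equilibrium pessimist fraction")
    if others:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
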