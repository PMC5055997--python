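"""Core model definitions for the SOSa-SPSa sentiment-contagion family.

The population is partitioned into susceptible (S), optimistic (O) and
pessimistic (P) compartments with a fixed total N.  Three right-hand sides
are provided:

* :func:`sisa_rhs` — the two-compartment SISa model (SIS with a constant
  spontaneous infection rate ``alpha`` in addition to contact transmission).
* the original SOSa-SPSa model — two SISa channels (S<->O and S<->P) that
  share the susceptible pool but do not interact; obtained from the
  modified model via :func:`reduce_to_original`.
* :func:`modified_rhs` — the modified SOSa-SPSa model, which adds direct
  optimist-pessimist interaction: an optimist meeting a pessimist becomes
  susceptible at rate ``l1`` or pessimistic at rate ``l2``, and a pessimist
  meeting an optimist becomes susceptible at rate ``m1`` or optimistic at
  rate ``m2``, subject to ``l1 + l2 <= 1`` and ``m1 + m2 <= 1``.

Contact (bilinear) terms can be frequency-scaled (divided by N, so dynamics
depend on compartment fractions) or density-scaled (raw counts).  Frequency
scaling is the default: the Hill et al. FHS rate estimates bundled as the
reference fixture are per-contact probabilities and only make sense on
fractions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np

__all__ = [
    "ModelParameters",
    "PopulationState",
    "StateDerivative",
    "ValidationReport",
    "InvalidPopulationError",
    "validate_parameters",
    "modified_rhs",
    "sisa_rhs",
    "reduce_to_original",
]

ContactScaling = Literal["frequency", "density"]

#: ten elementary rate names, in a fixed canonical order
RATE_NAMES = (
    "alpha_O", "beta_O", "g_O",
    "alpha_P", "beta_P", "g_P",
    "l1", "l2", "m1", "m2",
)


class InvalidPopulationError(ValueError):
    """Raised when a population total or state is unusable (e.g. N <= 0)."""


@dataclass(frozen=True)
class ModelParameters:
    """The ten contagion rates of the modified SOSa-SPSa model.

    Parameters
    ----------
    alpha_O, alpha_P
        Spontaneous optimism / pessimism rates (per unit time): susceptibles
        adopt the sentiment without any contact.
    beta_O, beta_P
        Per-contact transmission rates (per unit time) for the optimistic
        and pessimistic sentiment.
    g_O, g_P
        Recovery rates (per unit time): sentiment holders revert to
        susceptible.
    l1, l2
        Fate of an optimist contacting a pessimist: become susceptible
        (``l1``) or pessimistic (``l2``); ``l1 + l2 <= 1``.
    m1, m2
        Fate of a pessimist contacting an optimist: become susceptible
        (``m1``) or optimistic (``m2``); ``m1 + m2 <= 1``.
    contact_scaling
        ``"frequency"`` divides bilinear contact terms by N (default);
        ``"density"`` uses raw counts.
    """

    alpha_O: float
    beta_O: float
    g_O: float
    alpha_P: float
    beta_P: float
    g_P: float
    l1: float = 0.0
    l2: float = 0.0
    m1: float = 0.0
    m2: float = 0.0
    contact_scaling: ContactScaling = "frequency"

    def replace(self, **changes: object) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def contact_rate(self, N: float) -> float:
        """Scaling factor ``c`` applied to bilinear terms (1/N or 1)."""
        if N <= 0:
            raise InvalidPopulationError(f"total population N must be > 0, got {N}")
        return 1.0 / N if self.contact_scaling == "frequency" else 1.0

    def rates(self) -> dict[str, float]:
        """The ten rates as a name -> value mapping (canonical order)."""
        return {name: getattr(self, name) for name in RATE_NAMES}


@dataclass(frozen=True)
class PopulationState:
    """Compartment counts (or fractions) at one instant: S, O, P >= 0."""

    S: float
    O: float
    P: float

    @property
    def total(self) -> float:
        return self.S + self.O + self.P

    def as_array(self) -> np.ndarray:
        """State as the length-3 array ``[S, O, P]``."""
        return np.array([self.S, self.O, self.P], dtype=float)

    def fractions(self, N: float | None = None) -> "PopulationState":
        """The state rescaled to sum to one (fractions of ``N``)."""
        N = self.total if N is None else N
        if N <= 0:
            raise InvalidPopulationError(f"total population N must be > 0, got {N}")
        return PopulationState(self.S / N, self.O / N, self.P / N)

    def __iter__(self) -> Iterator[float]:
        return iter((self.S, self.O, self.P))


@dataclass(frozen=True)
class StateDerivative:
    """Instantaneous rates of change; components sum to zero (closed
    population), up to one rounding of the ordered floating-point sum."""

    dS_dt: float
    dO_dt: float
    dP_dt: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dS_dt, self.dO_dt, self.dP_dt], dtype=float)

    @property
    def max_abs(self) -> float:
        return max(abs(self.dS_dt), abs(self.dO_dt), abs(self.dP_dt))


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of parameter validation: a list of violated invariants."""

    violations: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_if_invalid(self) -> None:
        if self.violations:
            raise ValueError("invalid model parameters: " + "; ".join(self.violations))


def validate_parameters(params: ModelParameters) -> ValidationReport:
    """Check the model's parameter invariants, reporting every violation.

    All ten rates must be nonnegative, the interaction splits must satisfy
    ``l1 + l2 <= 1`` and ``m1 + m2 <= 1``, and ``contact_scaling`` must be
    one of the two recognised conventions.  The report lists each violated
    invariant; an empty report means the parameters are valid.
    """
    violations: list[str] = []
    for name, value in params.rates().items():
        if not np.isfinite(value):
            violations.append(f"non-finite rate {name}={value}")
        elif value < 0:
            violations.append(f"negative rate {name}={value}")
    if params.l1 + params.l2 > 1:
        violations.append(f"l1+l2>1 (l1={params.l1}, l2={params.l2})")
    if params.m1 + params.m2 > 1:
        violations.append(f"m1+m2>1 (m1={params.m1}, m2={params.m2})")
    if params.contact_scaling not in ("frequency", "density"):
        violations.append(f"unknown contact_scaling {params.contact_scaling!r}")
    return ValidationReport(tuple(violations))


def modified_rhs(state: PopulationState, params: ModelParameters, N: float) -> StateDerivative:
    """Right-hand side of the modified SOSa-SPSa system at ``state``.

    With contact scaling ``c`` (1/N for frequency, 1 for density)::

        dO/dt = -g_O*O + alpha_O*S + c*beta_O*O*S - c*(l1+l2-m2)*O*P
        dP/dt = -g_P*P + alpha_P*S + c*beta_P*P*S - c*(m1+m2-l2)*O*P
        dS/dt = -(dO/dt + dP/dt)

    ``dS/dt`` is computed from conservation as ``-(dO/dt + dP/dt)``, which
    is algebraically identical to its expanded form ``g_O*O + g_P*P
    - (alpha_O+alpha_P)*S - c*(beta_O*O+beta_P*P)*S + c*(l1+m1)*O*P`` but
    keeps the population closed to machine precision regardless of the
    magnitudes of the individual terms.
    """
    dO, dP = _reduced_rhs(state.O, state.P, state.S, params, N)
    return StateDerivative(-(dO + dP), dO, dP)


def _reduced_rhs(O: float, P: float, S: float, params: ModelParameters, N: float) -> tuple[float, float]:
    """(dO/dt, dP/dt) of the modified model; S supplied by the caller."""
    c = params.contact_rate(N)
    p = params
    OP = O * P
    dO = -p.g_O * O + p.alpha_O * S + c * p.beta_O * O * S - c * (p.l1 + p.l2 - p.m2) * OP
    dP = -p.g_P * P + p.alpha_P * S + c * p.beta_P * P * S - c * (p.m1 + p.m2 - p.l2) * OP
    return dO, dP


def sisa_rhs(
    S: float,
    I: float,
    alpha: float,
    beta: float,
    g: float,
    N: float,
    contact_scaling: ContactScaling = "frequency",
) -> tuple[float, float]:
    """Right-hand side ``(dS/dt, dI/dt)`` of the two-compartment SISa model.

    SISa is SIS with an extra spontaneous ("automatic") infection route:
    ``dI/dt = alpha*S + c*beta*S*I - g*I`` and ``dS/dt = -dI/dt``.
    """
    if N <= 0:
        raise InvalidPopulationError(f"total population N must be > 0, got {N}")
    c = 1.0 / N if contact_scaling == "frequency" else 1.0
    dI = alpha * S + c * beta * S * I - g * I
    return -dI, dI


def reduce_to_original(params: ModelParameters) -> ModelParameters:
    """Project onto the original (non-interacting) SOSa-SPSa model.

    Returns a copy with ``l1 = l2 = m1 = m2 = 0``; under the result the
    O.P coupling terms vanish identically and the dynamics decompose into
    two SISa channels sharing the susceptible pool.  Idempotent.
    """
    return params.replace(l1=0.0, l2=0.0, m1=0.0, m2=0.0)
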