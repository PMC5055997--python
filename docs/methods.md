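# Methods

## Model and assumptions

The crowd is a closed, homogeneously mixing population of fixed size N
partitioned into susceptible (S), optimistic (O) and pessimistic (P)
individuals. Individuals are exchangeable: no network structure, household
or contact heterogeneity, leader/rescuer roles or media influence is
modelled. Time is abstract ("per unit time"); no calendar mapping is
asserted.

Three nested deterministic systems are implemented:

1. **SISa** — susceptible⇄infected with contact transmission β, recovery g
   and spontaneous infection α: `dI/dt = α·S + c·β·S·I − g·I`.
2. **Original SOSa-SPSa** — two SISa channels (S⇄O, S⇄P) sharing the
   susceptible pool but never interacting. Obtained from the modified
   model by `reduce_to_original` (l₁=l₂=m₁=m₂=0); the package tests verify
   term-identity with two independent SISa evaluations.
3. **Modified SOSa-SPSa** — adds direct optimist–pessimist interaction.
   The bilinear O·P terms redistribute mass with net coefficients
   (l₁+l₂−m₂) out of O and (m₁+m₂−l₂) out of P; l₁+l₂ ≤ 1 and m₁+m₂ ≤ 1
   are enforced by validation. dS/dt is computed as −(dO/dt+dP/dt) so the
   population stays closed to machine precision.

One narrative transition sometimes attached to this model family — a
susceptible becoming optimistic specifically through pessimist contact —
has no term in the governing equations and is deliberately not implemented.

### Contact scaling

`contact_scaling="frequency"` (default) divides every bilinear term by N,
so the dynamics depend on compartment fractions; `"density"` uses raw
counts. The Framingham-derived rates bundled with the package are
per-contact probabilities: under frequency scaling they reproduce the
expected ≈63%/6%/30% equilibrium split, whereas density scaling drives the
system to a nearly all-optimist state. Density is retained only as an
explicit convention flag.

## Parameters

| name | meaning | default (reference fixture) |
|------|---------|------------------------------|
| α_O, α_P | spontaneous adoption, /time | 0.18, 0.04 |
| β_O, β_P | contact transmission, /time | 0.02, 0.04 |
| g_O, g_P | recovery to susceptible, /time | 0.088, 0.13 |
| l₁, l₂ | optimist→{S, P} on pessimist contact, /time | 0.13, 0.009 |
| m₁, m₂ | pessimist→{S, O} on optimist contact, /time | 0.09, 0.07 |

The fixture's initial state is the near-uniform split O=626, P=626, S=628,
N=1880.

## Numerical choices

- **Integration**: LSODA (adaptive, stiff-capable) with rtol 1e-10 and
  atol 1e-12·N. The system is mildly nonlinear and non-stiff at these
  scales; the tight tolerances exist so that conservation assertions at
  1e-8 relative are meaningful. Negative overshoot is never clipped: a
  tolerance band of −1e-9·N is accepted, anything beyond is a hard error.
- **Equilibrium by integration** (`equilibrate`): horizon 2000 time units
  with one doubling retry; accepted when max |d/dt| < 1e-10·N.
- **Equilibrium by root finding** (`find_equilibrium`): Powell hybrid on
  the reduced (O, P) system with S = N−O−P eliminated, so conservation
  holds by construction. Converged roots with a component below −1e-9·N
  are rejected with a diagnostic. The steady-state identity residual is
  reported alongside; at the contagion-free fixed point its denominators
  vanish (the identity's own side condition) and the residual is NaN.
- **Stability**: 2×2 Jacobian of the reduced system by central finite
  differences with step 1e-6·N, validated in tests against the hand-derived
  analytic Jacobian; stable ⇔ all eigenvalue real parts negative. This is
  a local, numerical check only — no analytic global stability result is
  claimed, and the 16-point simplex multistart only probes for coexisting
  roots (it finds exactly one for the reference fixture).
- **Sweeps**: each grid point warm-starts from the previous equilibrium;
  the first point starts from the base parameters' own equilibrium. Stored
  values are independently reproducible by cold per-point solves (tested
  to 1e-6). Default grids bracket the fixture: g_P ∈ 0.05…0.50 step 0.05,
  l₂ ∈ 0…0.30 step 0.03, α_P ∈ {0.01, 0.04, 0.07, 0.1}, (l₂, m₂) pairs
  (0.009, 0.07) and (0.07, 0.009).
- **Stochastic simulation**: Gillespie direct method on integer counts;
  propensities are the ten right-hand-side terms at the current state
  (frequency-scaled). Cumulative-propensity inversion selects the event;
  exact ties (probability zero) resolve to the lower-indexed event. Run i
  of an ensemble uses sub-seed seed+i. Initial states are rescaled to
  other N proportionally with largest-remainder rounding. No tau-leaping:
  at desk scales (N ≤ 10⁴, horizons ≤ 20) exact simulation is sufficient.

## Design notes on the parameter surface

The equilibrium pessimist fraction P\* responds to the interaction rates
only through the difference l₂−m₂ (given fixed l₁, m₁), since the O·P
coefficients are (l₁+l₂−m₂) and (m₁+m₂−l₂). Consequences verified by the
test suite:

- P\* decreases strictly in g_P with shrinking decrements (the regulative
  effect of pessimist recovery flattens as recovery speeds up).
- P\* increases in l₂ and decreases in m₂; for l₂ > l₁ the pessimist pool
  exceeds its value at the mirrored coordinates.
- P\* is nondecreasing in α_P. Over α_P ∈ [0.01, 0.1] the response is
  close to linear: the late increment (0.07→0.1) is smaller than the early
  one (0.01→0.04) for the default fate-split pairs, but this flattening is
  marginal and reverses slightly for balanced splits l₂ = m₂. The
  saturation property is therefore asserted only for the default
  (reference-regime) pairs.

## What the stochastic oracle does and does not show

The ensemble tests demonstrate that the ODE system is the correct
mean-field limit of the event-driven process under the packaged study
conditions (N = 10⁴, 200 runs, 11 saved points on t ∈ [0, 20], agreement
within 3 standard errors; pure-recovery runs against the closed form
N·e^(−g·t); fluctuation scaling ≈ 1/√N). They do not validate the model
against real crowd data: the rates come from a published cohort analysis,
and nothing here tests homogeneous mixing, rate constancy over time, or
the absence of network effects in real populations.

## Known limitations

- Stability is assessed numerically at solved equilibria only; with ten
  rate parameters no analytic stability classification is attempted.
- Uniqueness/globality of the equilibrium is probed by multistart, not
  proved.
- The sweep figures' underlying grids are bracketing choices around the
  reference rates, not reconstructions of any particular published axis.
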