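# Methods

## Model

`pcasim` simulates intravenous fentanyl dosing with a linear mammillary
three-compartment pharmacokinetic model plus a first-order effect site.
Writing a₁, a₂, a₃ for the drug amounts (μg) in the central,
fast-peripheral and slow-peripheral compartments and Ce for the effect-site
concentration (ng/mL):

    da₁/dt = u(t) − (k10 + k12 + k13)·a₁ + k21·a₂ + k31·a₃
    da₂/dt = k12·a₁ − k21·a₂
    da₃/dt = k13·a₁ − k31·a₃
    dCe/dt = ke0·(Cp − Ce),      Cp = a₁ / Vc

where u(t) is the zero-order infusion rate into the central compartment
(μg/min) and boluses are instantaneous additions to a₁.  The effect site
carries a concentration rather than an amount, so no effect-site volume is
introduced and ke0 appears exactly as written.

Units are chosen so that no conversions occur anywhere except μg/h → μg/min
for pump rates: amounts in μg, volumes in L, time in minutes; μg/L is
numerically identical to ng/mL.

### Default parameters

| parameter | default | units | meaning |
|---|---|---|---|
| Vc | 26.6 | L | central volume |
| k10 | 0.0332 | 1/min | elimination |
| k12 / k21 | 0.172 / 0.1 | 1/min | central ↔ fast peripheral |
| k13 / k31 | 0.131 / 0.0177 | 1/min | central ↔ slow peripheral |
| ke0 | 0.147 | 1/min | effect-site equilibration |
| MEC | 0.23 | ng/mL | minimal effective analgesic concentration |
| upper bound | 2.0 | ng/mL | side-effect threshold (user-overridable) |

These are adult fentanyl population point estimates; the simulation is
deterministic — interindividual and residual variability are zero by
construction, and the same parameter set is used for every simulated
subject.  The source study cites its parameter set without a weight
normalization, so the constants are used as printed for all subjects.  The
upper window bound is a configurable convention: 2 ng/mL is the effect-site
level flagged as risking opioid side effects, but the threshold is not
sharply established, so it is a default, not a claim.

## Numerical method

Dosing is piecewise constant, so between any two events the system is a
linear ODE with constant forcing and has an exact solution.  The engine
propagates the state with the matrix exponential of the 5×5 augmented
system (state + unit forcing), cached per (parameter set, step length):

    x(t+Δ) = Φ(Δ)·x(t) + u·ψ(Δ),   Φ = e^{AΔ},  ψ = ∫₀^Δ e^{As} ds · e₁

Consequences relied on throughout:

- **Grid independence.**  The sampling grid only chooses where the exact
  curves are evaluated.  Halving the grid step leaves shared samples
  unchanged to machine precision.
- **Exact off-grid values.**  A concentration at an arbitrary time is
  recomputed by propagating from the nearest earlier breakpoint — never
  interpolated.
- **Crossing times by root-finding.**  MEC/upper-bound crossings are
  bracketed on the sample grid (which contains every event time, so each
  bracket is smooth) and refined with Brent's method on the exact
  propagator (tolerance 1e−6 min, comfortably below the 1e−4 min target).
  A sub-MEC dip entirely inside one sampling interval could escape
  bracketing; at the default 0.1-min grid this would require dynamics far
  faster than any rate constant in the model.
- An adaptive Runge–Kutta integration (scipy `solve_ivp`, DOP853, rtol
  1e−11) exists **only in the test suite**, as an independent oracle; on
  100 random parameter/regimen draws the two routes agree to better than
  1e−6 relative.

Tie-break at simultaneous events: infusion-rate changes apply before
boluses at the same instant, so a bolus at a rate breakpoint rides on the
new rate.  Concentrations are sampled *after* the events at a time point,
so a bolus sample shows the post-jump plasma value; the effect-site curve
is continuous everywhere.

## Dosing programs

The time origin is the end of surgery (t = 0).  Built-in scenarios:

- **group_a** (conventional): 50 μg IV bolus at t = −10 min; PCA demand
  10 μg, lockout 10 min, no basal infusion.
- **group_b** (model-based): 50 μg loading as a zero-order infusion over
  [−10, 0] min (300 μg/h); PCA demand 10 μg, lockout 15 min; basal
  20 μg/h on [0, 60) min, then 10 μg/h.

The PCA lockout follows the pump convention: the clock runs from the last
*granted* demand, not the last attempt.  Patient demand behaviour is not a
modelled quantity; three explicit policies exist — `none` (the
deterministic base case both published concentration figures describe),
`worst_case` (a press the instant each lockout expires — the maximal-use
envelope), and `poisson` (seeded, for sensitivity studies).  Rescue boluses
are explicit user-supplied events because pain, their clinical trigger, is
not simulated.  The default base scenarios exclude rescue boluses.

## Window metrics

For a chosen reference concentration (effect-site by default, plasma by
flag) and window [MEC, upper], the package reports: the first downward MEC
crossing after the first dose (absolute and relative to that dose), total
time below the MEC and above the upper bound, the maximal disjoint
"undertreated" (sub-MEC) intervals, and the refined peak.  All durations
come from crossing times, never from counting grid points.

## Regimen search

The design step behind the model-based arm is an explicit exhaustive
search: every (initial basal rate, step-down time, subsequent rate)
combination over a user grid, simulated without demand boluses, is ranked
by feasibility (no excursion outside the window during a constraint
interval, default [0, 60] min) and, among feasible candidates, total
scheduled dose; ties break by lower peak concentration, then by
(initial rate, step time, subsequent rate) ascending.  The original study
states only that "various dosing schemes" were simulated and the optimal
one selected; the candidate grid and the minimal-exposure objective are
this package's explicit, configurable formalization of that intent.
Demands are excluded from the feasibility check deliberately: in a linear
system extra non-negative doses can only raise concentrations, so a
no-demand-feasible schedule remains feasible under any demand pattern, and
the check stays deterministic.

## Known discrepancies with the published read-offs

Two published figure-derived claims are *not* reproduced by the published
parameters themselves; the package computes, and its acceptance checks
honestly report, the exact values:

1. After a single 50 μg bolus, the first MEC down-crossing occurs at
   13.97 min (plasma) / 23.96 min (effect-site) after the bolus — not the
   ~30 min quoted from the figure.  At 28 min the effect-site curve sits at
   0.21 ng/mL vs the 0.23 ng/mL MEC line — indistinguishable at figure
   resolution.  Adding a single 10 μg demand bolus at PACU admission moves
   the crossing to 33.6 min, so the published figure plausibly includes a
   demand bolus.
2. Under the group_b base regimen the effect-site concentration first
   crosses the MEC at 39.4 min, not after 60 min.  Between ~39 and 60 min
   the curve lies within 3 % of the MEC (0.2234–0.2295 ng/mL) — again on
   the MEC line at figure resolution — and only after the 10 μg/h
   step-down does it clearly decline.  Consistently, the exhaustive search
   over first-hour rates {0, 5, …, 50} μg/h finds 25 μg/h the minimal
   feasible first-hour basal on a strict [0, 60]-min no-excursion
   constraint; the study's 20 μg/h spends 20.6 min marginally below the
   MEC.  Note also that the long-run steady state of 10 μg/h is
   0.189 ng/mL < MEC, so *any* schedule ending at 10 μg/h eventually sits
   below the window.

Both engine routes (matrix exponential and the independent ODE oracle)
agree on these numbers to <1e−6 relative, and the closed-form anchors
(bolus Cp₀ = dose/Vc = 1.8797 ng/mL; steady state Cp = rate/(k10·Vc) =
0.3775 / 0.1887 ng/mL at 20 / 10 μg/h) are matched to 0.1 %, so the
discrepancy lies between the published figure and the published
parameters, not in the propagation.

## Problem sizes and degenerate inputs

Default simulation horizon [−10, 2880] min (through the last 48-h clinical
assessment) at a 0.1-min grid (~29k samples, < 1 s); the acceptance
computations use 180–250-min horizons, which the curves' dynamics make
sufficient to locate every first crossing.  Degenerate inputs are rejected
with validation errors (negative doses/rates/steps, unordered attempt
times, overlapping basal segments, degenerate evaluation intervals, events
outside the simulated range).  Zero transfer constants are allowed — they
decouple the corresponding peripheral compartment and give the
one-compartment closed forms used as test anchors — while Vc, k10 and ke0
must be strictly positive.

## Limitations

- Linear PK only; no covariates, no nonlinearity, no interindividual or
  residual variability (point-estimate simulation by design).
- No pharmacodynamic model: pain scores, demand behaviour and rescue
  triggers are inputs, not outputs.  Passing tests therefore validate the
  dosing mathematics and pump logic, not clinical outcomes.
- The upper window bound and the candidate grids of the search are
  conventions to be set by the user, not estimated quantities.
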