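# Methods

This note documents the models, numerical choices and design decisions
behind `fedflux`, and what the shipped toy system does and does not show.

## Stage-wise flux balance analysis (`network`, `fba`)

The metabolic model is a stoichiometric network `S` (metabolites ×
reactions) with reversibility flags and role tags (exchange, biomass,
product).  For each of the five culture stages, biomass flux is maximized
subject to `S v = 0`, non-negativity of irreversible fluxes and
stage-specific box bounds.  Notes:

- The mathematically strict requirement "irreversible fluxes positive" is
  implemented as `v_irrev >= 0`: a linear program cannot represent a strict
  inequality, and zero flux is the closure of the constraint.  This is the
  universal FBA convention.
- Biomass optima are generically degenerate.  A second phase minimizes
  `sum(v**2)` at the fixed optimal biomass value (SLSQP with the mass
  balance and the optimum as equality constraints), making the target
  table unique and bit-reproducible.  If the second phase fails to keep
  feasibility to tolerance it is discarded and the vertex solution is
  returned.
- LP solves use `scipy.optimize.linprog` (HiGHS).  Mass-balance residual
  tolerance: `||S v||_inf <= 1e-8 * max(1, ||v||_inf)`; bound slack 1e-9.
- Reactions without explicit bounds default to ±1000 (irreversible: [0,
  1000]); the big-M value is configurable and exists to prevent silent
  unboundedness.
- Sign convention throughout: exchange flux positive = secretion,
  negative = uptake.  Units: mmol per 10⁹ cells per hour; biomass h⁻¹.
- TSV is the native network format (one reaction per row, an equation
  string such as `"A + 2 B -> C"`); SBML Level 3 files are read through
  cobra.  The `validate_network` pass reports findings (orphan and
  dead-end metabolites, duplicate exchanges) rather than raising, except
  for structural errors (duplicate ids, missing biomass reaction).

## The digital twin (`kinetics`, `twin`)

The plant emulator is a fed-batch reactor ODE model:

```
dV/dt       = F_in − F_out
d(V·Xv)/dt  = (mu − mu_d)·V·Xv − F_out·Xv
d(V·Xd)/dt  = mu_d·V·Xv − F_out·Xd
d(V·C_i)/dt = F_in·C_feed,i − F_out·C_i + q_i·Xv·V
d(V·P)/dt   = (alpha·mu + beta)·Xv·V − F_out·P
```

with Monod-type rate laws:

- `mu = mu_max · glc/(K_glc+glc) · [KI_glc/(KI_glc+glc)] · gln/(K_gln+gln)
  · asn/(K_asn+asn) · KI_lac/(KI_lac+lac) · KI_amm/(KI_amm+amm)`.  The
  optional Haldane glucose term models hyperosmotic stress at very high
  glucose and is off (`KI_glc = inf`) in the nominal set.
- `mu_d = kd_0 + kd_amm·[ammonia]` — ammonia is the only toxin in the
  death law, entering linearly.
- Glucose uptake `q_glc = mu/Y_xg + m_glc·glc/(K_mglc+glc)`
  (growth-linked plus saturating maintenance).
- The lactate shift is a smooth sigmoid blend (width 0.5 mmol/L) around a
  glucose threshold of 2 mmol/L: overflow secretion `Y_lg·q_glc` above it,
  Monod consumption `q_lac_max·lac/(K_lac+lac)` below.  The blend keeps the
  right-hand side differentiable for the optimizer; a hard switch would
  put a kink inside solver steps.
- Amino-acid uptake is Monod; ammonia is yield-linked to glutamine *and*
  asparagine uptake (`Y_amm_gln·q_gln + Y_amm_asn·q_asn`) because the
  asparaginolysis lump in the toy network releases ammonia and the twin
  mirrors the network structurally.  Alanine is yield-linked secretion
  from asparagine.
- Dead cells are tracked but inert (no lysis release terms).
- Units: hours, litres, mmol/L, 10⁹ cells/L, mg/L.  Flows given in L/min
  in configs are converted (×60) exactly once at the I/O boundary.

Integration uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e-8,
atol 1e-10), restarted at every policy knot so the piecewise-linear inputs
never present a derivative kink inside a step.  Concentrations are clipped
at zero in rate evaluation and after steps, with clip events logged on the
trajectory.  Cumulative glucose fed is integrated exactly (the integrand
`F_in·C_feed_glc` is piecewise quadratic; Simpson on knot-refined panels).

The supplementary-level equation set of the original study is not public;
the structure above is the package's own canonical CHO formulation,
consistent with every qualitative statement the study makes (Monod growth,
ammonia-driven death, lactate shift, growth-associated product).  All rate
laws are isolated in `kinetics.py` so users can substitute their own.

## The controller (`control`)

Single-shooting NLP over the knot values of the three piecewise-linear
manipulated profiles, with knots at control-interval boundaries and the
horizon truncated at batch end.  Choices that matter:

- **Internal prediction model.**  The controller integrates its model with
  fixed-step RK4 (dt = 0.5 h) rather than the adaptive plant integrator:
  a deterministic step count keeps finite-difference gradients smooth
  (adaptive step acceptance injects noise into them) and is ~50× faster.
  A JIT-compiled kernel (`_fastmodel`, numba with a pure-Python fallback)
  implements exactly these numerics; the test suite asserts agreement with
  the public fixed-step path.
- **Objective.**  Trapezoidal quadrature of the weighted squared flux
  deviations on a 2 h output grid.  Default weights
  `w_j = 1/max(|z*_j|, 1e-6)²` (largest magnitude over stages) make
  residuals dimensionless; without them large-magnitude fluxes would
  dominate Case A.  Targets follow the stage schedule along the horizon.
- **Solver.**  SLSQP on decision variables scaled to the unit box (raw
  knot values span three orders of magnitude).  Multistart from the
  shifted previous solution, minimal feed, quarter- and mid-bounds, a
  constant-hold candidate and two seeded random points; SLSQP polishes the
  best two starts and the returned policy never evaluates worse than the
  best start.  Fixed seed (default 0) makes everything deterministic.
- **Constraints.**  Box bounds on every knot; optional hard rate-of-change
  limits on consecutive glucose-feed knots (anchored at the previously
  implemented value, and at batch start at the feed line's initial
  concentration, default 0); optional working-volume band.  Volume is an
  exact integral of the piecewise-linear net flow, so the volume
  constraints are linear in the knots; they are imposed at knots and
  interval midpoints *plus one virtual control interval past the horizon
  with the terminal flows held* — without that terminal extension a plan
  can park an inflow spike just beyond its own lookahead and hand the
  overflow to the next cycle.  A projection (`feasible`) repairs bound,
  rate and volume violations of candidate points deterministically.
- **Rate limits as hard constraints.**  The ±5 / ±10 mmol/L values are
  amplitude bounds in the feed-concentration unit, so they are implemented
  as hard inter-knot constraints; a soft quadratic penalty mode exists for
  comparison (`rate_limit_mode="soft"`).
- **Continuity across cycles.**  The first knot of each manipulated
  variable is pinned at its previously implemented value.  The
  concatenated implemented segments then form one continuous
  piecewise-linear policy, which is what makes the closed-loop replay
  identity exact rather than approximate.
- **Regularization.**  A weak control-effort term (1e-4 on normalized
  knots) settles directions the tracking objective is flat in; it is far
  below tracking-residual scale and exists only to keep flat directions
  deterministic.
- Control-interval default set {8, 24, 72} h (any positive value allowed),
  horizon 72 h; the horizon must be an integer multiple of the interval.

## The closed loop (`loop`)

Measure → optimize → implement the first interval → advance the plant →
repeat, re-optimizing every control interval (a per-stage mode exists).
The plant side always uses the adaptive integrator at rtol 1e-8.  Percent
improvements are computed at batch end against the open-loop baseline.
`CampaignConfig.controller_params` lets the controller run on an *estimated*
parameter set different from the plant's truth; the default fixture keeps
them identical (no measurement noise, no estimation error), so closed-loop
runs are exactly reproducible.

## The toy fixture system (`fixtures`)

All fixture values are illustrative — chosen so the reduced system
reproduces the qualitative physiology of a fed-batch CHO culture — and are
not estimates from any experimental dataset.

The network (12 metabolites, 16 reactions) lumps glycolysis, lactate
exchange, pyruvate oxidation, respiration, glutaminolysis,
asparaginolysis/transamination, an ATP maintenance demand (NGAM), biomass
and antibody synthesis.  Two features are load-bearing:

- The **respiration cap** per stage makes overflow lactate secretion
  optimal at high glucose uptake and lactate consumption optimal once
  glucose is scarce — the lactate shift emerges from the LP rather than
  being painted on.
- The **maintenance demand** rises across stages, which keeps glucose
  targets at realistic magnitudes in the stationary phase while the
  biomass target falls.

Stage bounds were derived by fixing a desired biomass/lactate profile per
stage and solving the three internal balance equations for the glucose
cap, pyruvate-oxidation flux and respiration cap; the derivation is
reproducible from the coefficients in `fixtures.py`.

The twin's nominal parameters are sized so that every tracked
amino-acid/ammonia flux target sits *above* what the twin can realize
(one-sided targets — the study regime in which the targets are an ideal
the culture cannot quite attain), glucose Monod limitation is gentle,
and lactate is strongly inhibitory but rapidly clearable.  The vessel has
a narrow working-volume band (950–1100 L around a 1000 L working volume):
sustained feeding therefore requires outflow, which washes out product.
Together these give the system an interior optimum in feeding intensity
and align tracking fidelity with productivity — the regime in which
closed-loop control beats a fixed recipe and shorter control intervals
beat longer ones.  The conservative constant baseline feed (0.0025 L/min
of 250 mmol/L glucose feed against a small purge) represents a historical
process-sheet recipe.

What the fixture does **not** emulate: measurement noise, batch-to-batch
variability, temperature/pH/osmolality effects, intracellular dynamics,
product quality (glycosylation), and the full 100+-metabolite network
scale.  Passing tests therefore demonstrate the correctness and the
qualitative behaviour of the control machinery on a coherent reduced
system, not quantitative predictions for any real culture.

## Problem sizes and tolerances used in the test suite

- FBA oracle: brute-force vertex enumeration over the 16-reaction
  polytope (4 degrees of freedom), relative tolerance 1e-6.
- Twin oracle: independent fixed-step RK4 at dt = 0.01 h over the 360 h
  batch, agreement to 1e-4 relative; volume balance to 1e-6 relative over
  20 random piecewise-linear policies (seed 0).
- Objective: closed-form trapezoid values to 1e-12 on constant-residual
  toys.
- Optimizer: 200-point grid-search oracle on a one-dimensional subproblem;
  bound and rate-limit feasibility to 1e-9.
- Closed-loop battery: 360 h batches, Cases A/B at 8/24/72 h intervals
  plus two rate-limited variants; the whole battery runs in about a minute
  on one CPU.

## Known limitations

- The optimizer is a local SQP method on a nonconvex problem; the
  multistart set is small, and global optimality is not claimed.
- Finite-difference gradients limit the practical number of knots; at
  sub-hour control intervals an adjoint or algorithmic-differentiation
  gradient would be needed.
- The twin and the controller's internal model share rate laws; structural
  plant-model mismatch can be emulated only through parameter differences
  (`controller_params`).
- The vertex-enumeration oracle scales combinatorially and is only
  suitable for networks of roughly ≤ 20 reactions.
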