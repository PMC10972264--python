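# Methods

## Model

The package simulates an anaerobic membrane bioreactor (AnMBR) operated
at constant transmembrane pressure as two coupled compartments.

**Membrane.** Permeation follows a resistance-in-series Darcy law,

    J = ΔP / (μ (R0 + R)),        Qout = J · A,

with intrinsic resistance `R0` and a fouling resistance `R = Rc + Rp`
built from two mechanisms: a cake layer of mass `mc` on the surface
(`Rc = α mc / A`) and matter of mass `mp` blocked inside the pores
(`Rp = α′ mp / (ε A)`, acting on the porous fraction `ε` of the area).
Unlike constant-area fouling models, the useful filtering area shrinks
with both deposits,

    A = A0 / (1 + σ mc + σ′ mp),

so prolonged fouling is self-limiting: as `A` collapses, `Qout = J·A`
and with it the attachment flux go to zero.  The reciprocal form is the
dimensionally consistent reading of the area law given that σ, σ′ carry
units of 1/g; the alternative `A0 / (1 + mc/σ + mp/σ′)` is available
behind `MembraneParams.area_form` for sensitivity checks.

During filtration (ΔP > 0) the deposits grow in proportion to the mass
carried toward the membrane by the permeate stream:

    dmc/dt = Qout (Cs·ST + Cx·XT + Csmp·SMP) − f(mc)
    dmp/dt = Qout (β1·SMP + β2·ST)           − g(mp)

`ST` is the soluble total and `XT` the particulate total; SMP (soluble
microbial products) are treated separately in both mechanisms because
they dominate pore clogging.  `ST` excludes SMP by default (SMP has its
own weighted term; including it would double-count — the literal
`ST = S1+S2+SMP` convention is available via `st_includes_smp`).
`β2 = β1/15` by default: other solutes clog pores far less than SMP.
The sinks `f, g` are the gas-sparging control terms, linear by default
(`f = km·mc`, `g = kp·mp`) and user-replaceable by arbitrary positive
functions.

During relaxation (ΔP = 0) or backwash (ΔP < 0) the feed is stopped,
no permeate is produced, and the deposits decay exponentially toward an
irreversible residual:

    dm/dt = −ω m + m_irr.

Rather than prescribing `m_irr` directly, cleaning segments may carry an
irreversible fraction `x`: the source is re-derived each cycle (closed
form) so that exactly `x` of the end-of-filtration mass survives the
segment.  This realizes cycle-over-cycle membrane degeneration: the
post-cleaning area never returns to `A0` and peak resistances grow from
cycle to cycle.

**Biology.** The bulk is a two-step anaerobic digestion model with SMP
dynamics: acidogens X1 consume substrate S1 (Monod kinetics μ1),
methanogens X2 consume VFA S2 (Haldane kinetics μ2, substrate-inhibited
with maximum at √(K2·Ki)), and X1 re-consume SMP (Monod μ_smp).  SMP are
produced by growth and decay of both populations.  The membrane retains
biomass entirely; a fraction `beta_mem` of SMP passes it.  The inflow is
slaved to the permeate production, `Qin = Qout + Qw`, so the volume is
exactly constant during filtration.  The attachment sinks
`−(Qout/V)·C·(·)` in the bulk equations are, after scaling by `V`,
exactly the sources of the membrane mass balances (asserted in tests).
During cleaning the reactor runs as a batch, with optional re-injection
coefficients (`Cs_r`, `Cx_r`, `Csmp_r`, zero by default — detached
matter is neglected in the bulk).

## Numerics

* State vector `[X1, X2, S1, S2, SMP, V, mc, mp]`; phases are integrated
  segment-by-segment with `scipy.integrate.solve_ivp` (Dormand–Prince
  RK45, rtol 1e-8, atol 1e-10 by default, configurable), and segments are
  concatenated with exact state carry-over.
* Phase switches are discontinuities in `J`; the trajectory keeps both
  boundary samples, the second nudged by 1e-12 h, so the record stays
  strictly increasing in time while trapezoidal averaging of `J`
  integrates the jump exactly.
* Flux thresholds (stop events) are located by root-finding on the dense
  output of the integrator.
* States are projected onto the nonnegative orthant when evaluating
  right-hand sides, so cleaning/control sinks cannot drive masses
  negative within a step.
* Mean flux is the trapezoidal time average of `J` over the full
  horizon; cleaning time counts as zero production (an intermittent
  schedule is only worth its downtime if downtime is penalized).  The
  filtration-only average is available as an option.

## Calibration

The identification mirrors how such pilots are calibrated: measured
total COD is split into substrates and SMP at a fixed ratio
(85%/15% by default), COD and biomass series are linearly interpolated
onto the flux time base, `R0` is fixed beforehand from the first flux
measurement (`R0 = ΔP/(μ J(0))`), and the four weights (Cs, Cx, Csmp,
β1) are fitted by bound-constrained nonlinear least squares on the flux
(objective `F = Σ (J_i − Ĵ_i)²`), with β2 tied to β1/15.  The forward
model drives only the fouling sub-model with the interpolated
concentrations — not the full coupled model — matching the structure of
the identification data.

Multi-start initialization uses Latin-hypercube draws within the bounds
(16 starts, seed 0 by default).  Because the fixed COD split makes
SMP exactly proportional to ST, Cs and Csmp act on the model only
through the lumped combination `0.85·Cs + 0.15·Csmp`; the objective has
an exactly flat ridge, the 4-parameter jacobian is rank-deficient, and
trust-region steps stall in a shallow curved valley.  `estimate`
therefore adds a refinement stage that freezes the Cs:Csmp proportion
and refits (total soluble weight, Cx, β1), which removes the null
direction and descends to the valley floor (F ~ 1e-20 on noiseless
fixtures).  Stage one runs the forward model at rtol 1e-8 for speed;
the refinement at rtol 1e-11 so finite-difference jacobians are not
swamped by solver noise.

**Identifiability.** On noiseless synthetic data the identifiable
quantities — the lumped soluble cake weight, Cx and β1 — are recovered
essentially exactly (r² = 1).  The individual Cs and Csmp are *not*
identifiable under the fixed COD split; any report of them is a point
on the ridge.  Under 5% multiplicative flux noise the linearized
(Fisher-information) uncertainty of the lumped weight and β1 is far
above 100% — the two directions are nearly perfectly anticorrelated,
since both scale the overall fouling rate and differ only through the
ε/σ′ structure of the pore term — while Cx is determined to roughly
±8%.  A single declining-flux cycle simply does not carry four
parameters' worth of information; this is a property of the experiment
design, not of the optimizer (on noisy replicates the global minimum
itself moves: F(estimate) < F(truth)).

## Synthetic fixtures

`generate_dataset` emulates a two-cycle pilot campaign: 16 flux
measurements over days 1–39, 29 COD and 13 biomass measurements over
the 85-day horizon, at irregular times (uniform draws, window endpoints
included), with multiplicative Gaussian noise (CV 5% on flux, 10% on
concentrations by default).  COD and biomass values are sampled first
(smooth seasonal-scale profiles around 2.3 and 2.1 g/L with distinct
shapes); the flux is then generated by the fouling model driven by
exactly those sampled series, so at CV = 0 the calibration objective
vanishes at the true parameters by construction.  Driver noise is thus
realized in the inputs themselves (which the identification treats as
exactly known, as the real procedure does); errors-in-variables on COD
and biomass is not modeled.

Two reference configurations are provided.

* **Pilot fixture** (`pilot_fixture_config`): 1 m² membrane at 1.5 bar,
  ε = 0.7, σ = σ′ = 10 1/g, weights (0.1970, 0.1116, 0.9720, β1 =
  0.3999), `R0` from J(0) = 8.32 L/(h·m²), specific resistances
  α = α′ = 4e9 (so `R` is in 1/m for masses in g).  With a feed around
  2.3 g COD/L this reproduces the weeks-scale pilot behavior: flux
  declining from 8.32 to ≈ 3 L/(h·m²) over 39 days, end-of-cycle cake
  mass ≈ 43 g/m² and total resistance ≈ 1.1e14 1/m.
* **Control-experiment fixture** (`control_experiment_config`): a
  faster-fouling operating point for the 2 h control studies — an
  SMP-rich mixed liquor (SMP 2.2 g/L, biomass 13.3 g/L), higher
  specific resistances (α = 6e10, α′ = 2.5e11), a clean-membrane flux
  of 66 L/(h·m²), and quasi-stationary biology (growth, consumption and
  decay rates far below 1/h, high SMP retention), since anaerobic
  digestion evolves on day scales while a functioning period lasts 2 h.
  Relaxation detaches deposits quickly (ω = ω′ = 450 1/h) but leaves
  half of them behind (irreversible fraction 0.5 per cleaning —
  relaxation without backwash removes only part of the deposit).  The
  constants of this fixture were chosen once, by least squares against
  the stated operating points of the control studies (the mean-flux
  ladder for 1/2/5/10 cycles, the uncontrolled baseline, the
  sparging-only and the combined strategy), and then frozen; they are
  not refit anywhere in the package or its tests.

## Control strategies

* `none` — a single uninterrupted filtration segment.
* `gas_sparging` — filtration with the detachment sinks active
  (defaults km = 5 1/h, kp = 0: sparging scours the cake but does not
  reach matter inside pores).
* `intermittent` — n filtration/relaxation cycles at fixed ratio
  αt = Tfiltr/TRelax (default 7) over the horizon: Tfiltr =
  (period/n)·αt/(1+αt), TRelax = (period/n)/(1+αt).
* `combined` — sparging until the flux first declines to a threshold
  Js (event-detected), then sparging off and intermittent cycles over
  the remaining horizon (sequential use; an overlap option exists but
  defaults off).  If the threshold is never reached within the horizon
  the run degrades to sparging-only with a logged note.

Strategies are compared by the mean produced flux over the full
horizon.  Sparging strips the cake and so lowers `mc` and `Rc`
monotonically in km, but by removing the protective cake layer it
routes more solutes into the pores: terminal `mp` is nondecreasing in
km.  More intermittent cycles raise the mean flux with diminishing
returns (each relaxation restores the flux near its post-irreversible
ceiling, but each cycle also pays the relaxation downtime and
accumulates the irreversible residue).

## What the tests do and do not show

The synthetic fixtures exercise every code path end-to-end and pin the
model to the printed operating points listed above, but they inherit
the model's own structure: measurement series are generated by the same
fouling law that is fitted to them, so calibration tests demonstrate
correctness of the estimation machinery, not the adequacy of the model
for any real membrane.  Real COD/biomass data are noisier, non-Gaussian
and autocorrelated; real fouling includes mechanisms (complete/
intermediate blocking, back-diffusion, biofilm growth) that this model
deliberately omits.

## Known limitations

* Constant-pressure operation only; constant-flux/variable-TMP mode is
  out of scope.
* No biogas/methane outputs, no pH/alkalinity, no EPS dynamics.
* Cs/Csmp are not separately identifiable under a fixed COD split, and
  β1 and the lumped soluble weight are near-collinear under noise (see
  Identifiability above).
* The cleaning-phase re-injection terms are proportional to bulk
  concentrations as specified, which is physically surprising but kept
  literal; defaults are zero.
* The control-fixture parameter set stands in for an unavailable
  reference configuration; simulated strategy outcomes at that point
  are approximate reproductions of the reference behavior (orderings
  are robust, absolute mean-flux values carry ~10–20% configuration
  uncertainty).
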