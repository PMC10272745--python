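# Methods

## Model structure and assumptions

The model describes intrathecal delivery along the neuraxis with six coupled
compartments.  The spinal CSF (C1) is a one-dimensional channel of uniform
cross-section A (cm²), closed at the sacral end and exchanging with cranial
CSF at the cervical end; the spinal cord (C2) is a parallel rod of
cross-section A_t with no axial transport (interstitial diffusion is slow on
the scale of the rod).  Cranial CSF (C3), cranial tissue (C4), blood (C5)
and peripheral tissue (C6) are well mixed.  All kinetics are linear: the
model is positively homogeneous of degree one in concentrations, so doubling
the dose doubles every concentration everywhere.

Key simplifications: plug flow (no radial velocity or concentration
gradients), no oscillatory CSF velocity component (pulsatile mixing is
coarse-grained into the effective dispersion coefficient), rigid CSF spaces
(no compliance), and a cranial compartment without spatial resolution.
Infused fluid volume is not tracked as a change in CSF volume; it enters
only through the plug-flow velocity and the drug source term.

### Exchange laws

Fluxes are amounts per minute; each ODE divides by the receiving volume, so
exchange is conservative by construction:

| pair | law | note |
|------|-----|------|
| spinal CSF ↔ spinal tissue | U₁₂(C₁ − β₁₂C₂) | per element, U₁₂/N |
| spinal CSF ↔ blood | U₁₅(C₁ − β₁₅C₅) | per element, U₁₅/N |
| spinal tissue ↔ blood | U₂₅(C₂ − β₂₅C₅) | law chosen by analogy with the other pairs; per element, U₂₅/N |
| cervical boundary ↔ cranial CSF | U₁₃(C₁(L) − C₃) | boundary only, no trapping coefficient |
| cranial CSF ↔ brain | U₃₄(C₃ − β₃₄C₄) | |
| brain ↔ blood | U₄₅(β₄₅C₄ − C₅) | asymmetric: β multiplies the brain side |
| blood ↔ peripheral | U₅₆(C₅ − β₅₆C₆) | |

U absorbs the interface area (a lumped U·A, mL/min); the spinal-interface
coefficients are totals for the whole rod, split uniformly as U/N per
element so that behaviour is independent of the grid resolution.  The
stickiness β ∈ [0, 1] biases reversible exchange toward slow tissue release
(β = 1 recovers a plain concentration difference; β < 1 traps drug in the
second compartment).  The asymmetric brain↔blood form is retained as
modelled rather than "corrected" to the symmetric pattern.

### Brain partition

Cranial-tissue drug is split among pons, hippocampus, cerebellum and cortex
by Cᵢ = φᵢV₄C₄/Vᵢ with Σφᵢ = 1 and ΣVᵢ = V₄ (the cortex volume is defined as
V₄ minus the three named regions).  The rule conserves amount exactly and
makes every regional series proportional to C₄, which is what the
closed-form partition estimator exploits.

### Infusion

An infusion event delivers V_inj mL carrying dose/V_inj µg/mL over a finite
duration at constant rate; a flush is the same with zero concentration.  The
inflow is spread by a raised-cosine (Hann) point-spread kernel with compact
halfwidth h (default 2 cm): smooth, symmetric, exactly integrable.  Near a
domain boundary the kernel is clipped to [0, L] and renormalised so volume
and mass accounting still hold.  The plug-flow velocity is the exact running
integral of the kernel scaled by rate/A: zero at the closed sacral end,
F(t)/A rostral of the kernel support, zero whenever no event is active.
Overlapping events superpose linearly.

## Numerics

* **Discretization.**  Cell-centered finite volumes, N uniform elements per
  rod (2N + 4 unknowns).  Dispersion: central second difference with
  reflecting (zero-flux) ends; the cervical coupling to C3 is a separate
  boundary exchange term evaluated at the last cell.  Advection: first-order
  upwind on face velocities — the flow is unidirectional rostral, and
  monotone positivity-preserving transport was preferred over higher order;
  the convergence study quantifies the cost (observed order ≈ 1 when
  advection dominates, ≈ 2 for smooth dispersion-dominated problems).
* **Cervical outflow.**  Plug flow with a closed sacral end forces the
  infused volume out of the cervical end; the advected amount u(L)·A·C₁(L)
  is delivered to cranial CSF while an infusion runs, so the simulator
  conserves mass for any schedule.  A configuration switch
  (`cervical_advection: false`) restores a purely diffusive boundary
  coupling for comparison, at the price of losing the advected mass.
* **Infusion source.**  Per-cell kernel integrals are computed from the
  exact kernel antiderivative, so the delivered mass equals the nominal dose
  to round-off rather than to quadrature error.
* **Time integration.**  Between event boundaries the system is linear and
  time-invariant, dy/dt = My + s with constant M, s.  The integrator splits
  the horizon at event start/end times (1-min boluses are never stepped
  over), integrates each segment in local time with scipy's BDF and the
  exact Jacobian, and evaluates dense output at the requested times.
  Defaults rtol = 1e-8, atol = 1e-11: tight enough that mass-conservation
  and analytic-oracle checks at 1e-6 relative tolerance have an order of
  magnitude of headroom, while a 7-day, 204-equation simulation still runs
  in ~0.3 s on one CPU.
* **Negativity policy.**  Values within the solver tolerance below zero
  (−max(10·atol, 1e-9·peak)) are clamped to zero; anything lower aborts with
  the last valid state — silent negative concentrations are never returned.
* **Degenerate inputs.**  Zero-dose schedules are valid (identically zero
  trajectories); t_end before the last infusion, N < 2, non-simplex φ, β
  outside [0, 1] and overlapping invalid events are rejected with aggregated
  validation reports.

## Calibration

The fitting layer systematises calibration as bounded nonlinear least
squares (scipy `least_squares`) instead of manual trial-and-error tuning.
Residuals are taken in log10-concentration space above a quantification
floor (default 1e-9 µg/mL), because concentration–time profiles span several
decades and linear residuals would see only the peaks.  Positive parameters
are optimised on a log10 scale; partition coefficients are estimated in
closed form from the proportionality of regional series to C₄ and projected
onto the probability simplex.  A candidate whose simulation fails is charged
a large finite penalty so the optimiser can route around infeasible corners.
Fits report convergence flags, a Jacobian-based covariance proxy, residual
tables, and — when the dataset carries known ground truth — per-parameter
recovery errors.

## Synthetic data

`generate_synthetic` samples any set of observables at chosen times from a
simulation and applies multiplicative lognormal noise with unit mean and a
specified coefficient of variation (CV = 0 reproduces the model output
exactly; the generating seed is recorded in the dataset provenance).  It
emulates assay noise on concentration measurements; it does **not** emulate
inter-animal variability, digitisation error, assay floors/ceilings, or
model misspecification.  Parameter-recovery tests on such data therefore
demonstrate identifiability and correctness of the fitting machinery under
the model's own dynamics — not that the model fits any particular animal.

## Reference parameter set

The shipped configuration (`src/itpk/data/reference_nhp.yaml`) represents an
adult non-human primate: L = 20 cm, A = 0.5 cm² (10 mL spinal CSF),
A_t = 0.3 cm² (6 mL cord), V₃ = 8 mL, V₄ = 72 mL, V₅ = 150 mL,
V₆ = 2000 mL, and the single-dose protocol 12 mg / 1 mL / 1 min at the
lumbar site plus a 0.25 mL, 1-min flush.  The effective dispersion
D = 0.1 cm²/min is the NHP-calibrated value for ASO transport; the exchange,
stickiness, clearance and partition values are documented stand-ins chosen
in physiological ranges and meant to be overridden by drug- and
subject-specific calibration.  Landmark positions default to lumbar 0.15·L,
thoracic 0.50·L, cervical 0.90·L and are configurable.  All results shipped
with the package (tests, examples, acceptance script) either do not depend
on the stand-in values or treat them as the synthetic ground truth of a
recovery study.

## Problem sizes used in the shipped checks

Tests and the acceptance script scale problems to desk size as the package's
own verification choices: analytic oracles run at N = 100–200 on minute-to-
hour horizons; the convergence study uses N ∈ {50, 100, 200, 400}; the
regimen-trend checks use a 5 × 5 volume × duration grid at N = 100 and a
400-sample random sweep at N = 50 over a 7-day horizon; dispersion recovery
uses the full reference configuration (N = 100, 24 samples over 7 days).

## Known limitations

* Upwind advection smears sharp fronts at coarse N; use the convergence
  study to pick N when front position matters.
* The brain is a single kinetic pool; regional heterogeneity enters only
  through static partition fractions, so all regions share one time course.
* No catheter mechanics, backflow, infusion-pressure or safety modelling;
  infusate volume as a fraction of CSF volume is the user's own constraint.
* Human translation is supported through configuration (geometry, volumes,
  rates) but no human reference values are shipped.
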