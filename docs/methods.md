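# Methods

This note documents the models, estimators and numerical choices behind
`glosens`, in the spirit of the methods documentation that simulation
packages ship alongside their APIs.

## The quantity being analysed

For a kinetic ODE model with state `y(p)` (steady-state concentrations,
steady-state reaction fluxes, or an oscillation period) and parameters `p`,
the package works with scaled (dimensionless) sensitivity coefficients

    C = (p / y) · ∂y/∂p

estimated by relative finite differences: the parameter is perturbed by a
fraction `rel_step` of its value (default 0.001, i.e. 0.1%) and the output
response measured.  Forward differencing is the default scheme; it carries
an O(rel_step) truncation bias (for a coefficient that is exactly −1, the
forward estimate at step h is −1/(1+h) ≈ −0.999 at h = 10⁻³).  A central
scheme with O(rel_step²) error is available and is what the internal
oracles and the MCA matrices use.

When the perturbed parameter scales a reaction rate linearly (a limiting
rate V), the coefficient is a *control coefficient* in the sense of
metabolic control analysis (MCA), and the summation theorems apply: flux
controls across reactions sum to 1, concentration controls to 0.

## Model representation

`KineticModel` stores species (concentrations; boundary species are
frozen), compartments, reactions with symbolic rate laws (sympy
expressions), a flat parameter list with reference values, and optional
explicit rate rules for raw-ODE models.  Rate laws are extensive
(amount/time); concentration derivatives divide by the compartment volume.
SBML Level 2/3 files are read through libsbml: function definitions and
assignment rules are inlined at load, reaction-local parameters are lifted
into the flat list as `"<reaction name>.<id>"` (the naming used in
published sensitivity tables; local ids shadow global ones, as SBML
requires), events in the file are ignored with a warning, and algebraic
rules or delays raise an explicit unsupported-feature error.

The model compiles once into lambdified evaluators for the right-hand
side, its Jacobian, the reaction rates and the elasticity matrix.
Conserved moieties are detected exactly (rational row reduction of the
stoichiometric matrix); steady-state solving and the MCA linear algebra
operate on the reduced system of independent species, with totals fixed by
the starting state.

## Output evaluators

* **Steady states** — damped Newton iteration from the reference state on
  the conservation-reduced system (analytic Jacobian; residual tolerance
  10⁻⁹ on the RHS norm), with fallback to relaxation integration over
  growing horizons (10², 10⁴, 10⁶ time units) followed by a Newton polish.
  Newton roots with negative reaction-governed concentrations are rejected
  as nonphysical (rate laws such as Hill kinetics admit spurious negative
  roots); rate-rule variables may legitimately be negative.  Stability is
  reported from the dominant eigenvalue of the reduced Jacobian but never
  used to discard a result.  Failure of both routes yields an undefined
  status (`no-steady-state`) rather than an exception, because wide-band
  sampling must aggregate such outcomes.

* **Time courses** — LSODA with analytic Jacobian, rtol 10⁻⁸ / atol 10⁻¹²,
  uniform output grid.  A terminal event cuts off trajectories whose
  magnitude exceeds 10⁹ × the initial scale, so finite-time blow-ups
  return an incomplete-trajectory status instead of grinding the step
  size to nothing.

* **Oscillation periods** — maxima of the observed variable are located on
  the dense trajectory by discrete peak finding plus parabolic refinement,
  which decouples the estimate from the output-grid resolution.  The first
  half of the simulated window is discarded as transient (configurable).
  The period is the mean of successive maximum-to-maximum intervals —
  equivalently (t_last − t_first)/(n − 1) — rather than a single
  subtraction of two event times; averaging suppresses peak-location noise.
  The estimate is undefined when fewer than 3 maxima remain, when interval
  scatter exceeds a 5% coefficient of variation, or when peak amplitudes
  above the window median decay by more than half across the window (a
  damped, not sustained, oscillation).  Amplitudes are measured against
  the window median rather than by scipy's peak prominences because the
  prominence of the final peak is truncated at the window edge.

## Control coefficients

`control_coefficients` injects a synthetic multiplicative factor
(reference value 1) into every rate law and differentiates the steady
state with respect to it.  This realises "a parameter that scales the rate
linearly" for arbitrary rate laws without hunting for a V parameter in
each; for rate laws that do contain a linear V, the result is identical to
perturbing that V.  Parameters are additionally tagged `limiting-rate`
when every rate law they appear in is homogeneous of degree 1 in them
(tested numerically by doubling and tripling).

Two routes are implemented: central finite differences on the multipliers
(default step 10⁻⁴, truncation error ≈ 10⁻⁸; each perturbed steady state
warm-starts from the base state) and the classic MCA linear algebra from
the reduced Jacobian and elasticities.  The second route is exact up to
the steady-state solve and serves as an independent cross-check of the
first in the test suite; both satisfy the summation theorems to well
inside the 10⁻⁴ tolerance asserted in the tests.

## Sampling-based global analysis

Parameters are drawn independently and uniformly on
`[ref·(1−δ), ref·(1+δ)]` per parameter (endpoints swapped for negative
references).  Sample *i* of a run is generated from a counter-based seed
`(master_seed, i)`, so results are independent of chunking, resumption
point or parallel execution — verified by a chunking-invariance test.
Runs at different bands with the same master seed share their underlying
uniform draws, which makes band-nesting properties testable.

Undefined samples (lost steady state, lost oscillation, unscalable output)
are counted per reason code and reported with every distribution; they are
excluded from histograms but included in the peak-height normalisation
(modal-bin frequency over *total* samples).  Histograms are unit-area over
the defined samples; bin count defaults to Freedman–Diaconis with a floor
of 50 bins.  Value spreads at the rounding noise of the finite-difference
pipeline (≤ 10⁻⁹ relative) are collapsed to degenerate distributions —
a structurally constant coefficient is a point mass, not a histogram.
The peak location is the modal bin of the density smoothed with a Gaussian
kernel at twice Silverman's bandwidth: raw modal bins of flat-topped
densities are sampling-noise dominated, and kernel mode estimation is
stable at a larger bandwidth than density estimation.  The Shapiro–Wilk
statistic is computed on the defined values, deterministically subsampled
to at most 5000 points (the test's validity range; the cap is recorded in
every summary).

## Optimisation-based global analysis

Bounds on each coefficient come from a pair of particle-swarm
optimisations (minimise, maximise) over the same hypercube.  The swarm is
the standard global-best formulation; inertia 0.7298 and cognitive/social
accelerations 1.4962 (constriction-factor values) are the defaults, with
swarm size and iteration limit as the cost knobs.  The reference point is
always seeded into the initial swarm, so a zero-width domain evaluates
once and returns the local value.  Positions are clamped to the domain
with the velocity zeroed on the clamped coordinate.  Undefined objective
values score as worst-possible fitness so swarms retreat from non-viable
regions; the number of such encounters is reported.  Each reported bound
is re-evaluated at its arg-point as a guard against objective/report
mismatch, and the two optimisation jobs per coefficient are independently
seeded, making results independent of execution order.  Whether the
bounds dominate the sampled extremes is computed and reported
(`bounds_vs_sampling`), never assumed: either method can win.

## Pattern-of-control robustness

Each per-parameter, per-band distribution is reduced to qualitative flags:
sign span (positive-only / negative-only / mixed; optimisation bounds can
widen the span but, carrying no density, can never add modes), an
attains-zero flag (density above 1% of the peak within ±1% of the range
around zero), multimodality (peaks of the Silverman-smoothed histogram
with prominence ≥ 5% of the maximum, zero-padded so boundary modes count),
and a high-magnitude flag (max |value| ≥ threshold, default 1; magnitude
comparisons carry a 10⁻⁹ relative tolerance so a structurally unit
coefficient evaluating to 1 − 10⁻¹³ still counts).

"Multiple patterns" means mixed sign, or several modes, or zero coexisting
with clearly nonzero control (a mode farther from zero than 5% of the
value scale).  The *robustness level* of a model output is the smallest
band at which any parameter shows multiple patterns; if no listed band
does, the level is reported as above-max-band.  Bands where no parameter
has any defined sample are marked non-viable and excluded from the level
determination.  The per-band exceedance fraction (share of parameters
able to reach |C| ≥ threshold) is reported separately for sampling and
optimisation evidence.

## Synthetic fixtures and what they do (and do not) show

Every fixture ships an oracle computed by an independent route — closed
form or symbolic linear algebra, never the finite-difference pipeline:

* the irreversible chain pins all flux control on its first step
  (coefficients exactly 1, 0, and −1 for the intermediate concentration);
* the reversible chain's steady state is solved symbolically, giving exact
  control coefficients at arbitrary parameter values (the grid oracle for
  the swarm bounds);
* the linear oscillator (rate-rule form, on purpose: it exercises the
  raw-ODE path, and mass-action centres are structurally fragile) has
  period exactly 2π/ω and scaled period sensitivity to ω exactly −1;
* the bimodal-control toy feeds a substrate at constant rate `Vin` into a
  cooperative Hill-4 branch of capacity `V1` (K = 0.5) plus a weak linear
  leak (k₂ = 0.1, guaranteeing a steady state everywhere).  With the
  reference at `Vin = 1.0, V1 = 1.5` the branch is unsaturated and its
  flux-control coefficient is ≈ 0.04; sampled capacities with `V1 < Vin`
  saturate the branch and pin the coefficient near 1.  A ±90% band mixes
  the regimes (bimodal, modes near 0 and 1); a ±1% band does not
  (unimodal).  The reference values were chosen once so that the reference
  sits in the low-control regime with the regime boundary well inside the
  wide band.

These fixtures validate the estimators, not biology: they are low
dimensional, non-stiff, and have unique physical steady states.  Passing
them says the machinery is correct; it says nothing about sampling density
or convergence on models with hundreds of parameters, where both sampling
and optimisation can (and in published analyses do) miss extremes.

## Problem sizes and defaults

The shipped analyses run on the fixtures at desk scale, chosen as the
smallest sizes at which each effect is unambiguous: 10⁴ samples per band
for the bimodal-control scenario, a few hundred samples per band for
exceedance/robustness profiles, 100 random parameter perturbations for the
summation-theorem sweep, a 200×200 grid for the swarm-bound oracle, and
swarms of 10–20 particles for tens of iterations on the 1–2 parameter
fixtures.  Published studies of full-size signalling models use 10⁵–10⁶
samples and swarm budgets of 10³–10⁵ evaluations per coefficient;
the same code paths apply, with `n`, `SwarmSettings` and the band list as
the scaling knobs.

## Known limitations

* Forward differencing inherits the 0.1%-perturbation bias noted above;
  results near bifurcations additionally reflect the sensitivity of the
  output itself to the step.
* Period detection assumes a reasonably regular oscillation; strongly
  modulated or chaotic attractors are reported as irregular rather than
  assigned a period.
* SBML support covers core constructs used by kinetic ODE models; species
  with `hasOnlySubstanceUnits` in non-unit compartments are handled by
  tracking amounts in a synthetic unit compartment, and models relying on
  events, delays or algebraic rules are rejected loudly rather than
  approximated.
* Histogram-based multimodality detection has finite resolution: modes
  closer than roughly twice the smoothing bandwidth merge.
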