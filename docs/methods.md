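# Methods

This note documents the model, the numerical scheme, the synthetic-data
generator, and the design decisions behind `metaburden`, in the spirit of a
model-description appendix.

## Model

### Growth

All tumors — the primary and every metastasis — share Gompertz kinetics
`dx/dt = a ln(K/x) x` from a single founding cell (`x0 = 1`). The carrying
capacity is fixed at `K = 10^12` cells for all fitted examples; it is a
configurable constant, not a fitted parameter. Sizes are continuous cell
counts with hard lower bound `x ≥ 1`; volumes convert via
`10^-3 ml = 1 mm³ = 10^6 cells`. Time is measured in days from tumor
origin. The derived initial rate `r = a ln K` is always recomputed, never
stored, so `K = exp(r/a)` holds exactly. The reported "cell-cycle length"
follows the clinical convention of reading the numeric value of `ln 2 / a`
(with `a` per day) in hours.

### Metastatic population

The size-structured density ρ(x, t) obeys a transport equation with the
seeding boundary condition `g(1,t) ρ(1,t) = ∫ m x^α ρ dx` and the primary
embedded as `ρ(1,0) = 1`. Defaults: α = 2/3 (surface seeding of a
spheroid); re-seeding by metastases **on** (the boundary integral runs over
the full density), toggleable for analyses that want primary-only seeding.
Counts are expected values of an intensity, not stochastic realizations —
fractional tumor counts are meaningful model output.

### Therapy

*Chemotherapy.* An application day switches the growth law of **all**
tumors to `dx/dt = −μ(t) x`; growth is neglected while a short-half-life
cytotoxic drug is active. Kinetic resistance decays the kill fraction
exponentially in cumulative applied time, `μ(t) = μ0 exp(−μ* A(t))`, with
no recovery between cycles and no inter-drug transfer. Application
granularity is one calendar day per administration; this matches the daily
solver grid and the hours-scale half-life of cytotoxics. A consequence
worth noting: a *scheduled* application with μ0 = 0 still suppresses growth
for that day by model definition — "zero-efficacy therapy reduces to
therapy-free" holds for the immunotherapy pathway (χ = 0), and for
chemotherapy only in the sense of an empty application calendar.

*Immunotherapy.* One-compartment pharmacokinetics per body volume (assumed
constant per patient), dose in mg converted to molecules via the molar
mass; clearance `ln 2 / t½`. Doses are one-day constant-rate infusions by
default; an instantaneous-bolus switch exists and leaves the cycle-mean
steady state `c_st = (N_A/M)(d/l) t½ / ln 2` unchanged. Efficacy is a
first-order Hill kill `χ c/(c50 + c)` per cell per day added to the
Gompertz law. The packaged drug catalog lists the approved regimens
(dose, cycle length, molar mass, half-life); the weight-based durvalumab
regimen is tabulated at a 75 kg reference mass. Catalog molar masses are
the rounded public values; published per-patient `c_st` figures computed
from unrounded masses can differ from the catalog-derived ones by a few
percent, which is why tests assert the analytic steady-state *property*
rather than specific `c_st` values.

Joint administration of both modalities is rejected (clinically not
applicable); a chemotherapy era must end before the first antibody dose.

*Extinction.* The model has no death process; a kill term can push a tumor
below one cell. Default: clamp at one cell (the domain boundary), from
which regrowth is possible. Option `eradicate_below_one` removes such
tumors instead. The clamp is the conservative choice given that no
extinction rule is part of the model.

## Numerical scheme

### Characteristics / cohort solver

Because all tumors share one growth law `g(x, t)`, characteristics never
cross and the density reduces to: the primary trajectory plus one *cohort*
per time step (expected metastases seeded during that step, entering at one
cell). In log-size `u = ln x` every step update is affine and exact where
the dynamics allow:

- therapy-free: `u ← ln K − (ln K − u) e^{−a Δt}` (exact Gompertz flow);
- chemotherapy day: `u ← u − ∫ μ dt` with the integral in closed form;
- immunotherapy: `u ← ln K − (ln K − u) e^{−a Δt} − J`, where
  `J = ∫ e^{−a(t₁−s)} χ c(s)/(c50+c(s)) ds` is the same scalar for all
  tumors and is evaluated per step by 5-node Simpson quadrature on the
  exact piecewise-exponential concentration (dose boundaries are always
  step boundaries).

Seeding increments use trapezoidal quadrature of the boundary integral over
each step; the newborn cohort is dated at the step midpoint and initialized
by the half-step flow map, which makes the scheme second-order in the step
size (halving the default `Δt = 1 d` moves totals and burden by ~5·10⁻⁵
relative on reference-patient parameters). Step boundaries always include
therapy switch times and recording times, so branch switches never occur
inside a step. The inner loop is a numba kernel; a therapy schedule whose
kill terms are identically zero produces bit-identical trajectories to a
therapy-free run on the same step grid.

### Finite-volume cross-check

The test suite carries an independent conservative upwind finite-volume
discretization in log-size (primary handled as an exact trajectory feeding
the boundary influx). On a fast-growing small instance
(`a = 0.1/d, K = 10⁶, m = 10⁻⁴, α = 2/3, 200 d` — chosen so that
re-seeding dominates and the population reaches ~3·10⁸ tumors) the two
solvers agree within 2 % on totals, burden, and the per-decade size
histogram (normalized by total count). Both converge toward a common value
under refinement; at the tested resolutions the cohort solver sits ~1.2 %
above and the finite-volume solver ~0.2 % below it, the latter's
first-order numerical diffusion being the slower-converging error.

## Fitting

The objective is least squares of the predicted **total tumor burden**
against the measured series. Burdens are compared in cells; because treated
burdens span decades, an optional log-burden objective exists and is the
maximum-likelihood choice under the generator's multiplicative noise (the
recovery experiments use it; the linear objective remains the default).

Time anchoring: `t = 0` is tumor origin. Given a trial growth rate `a`, the
diagnosis day is `T(primary size at diagnosis)` via the closed-form tumor
age, so the time axis shifts consistently with `a` during optimization
instead of being a separate free parameter.

Optimization: Latin-hypercube multi-start (default 8 starts, seeded and
deterministic) in the bound box, `a`, `m`, `c50` handled on a log₁₀ scale;
two local algorithms per start (trust-region-reflective least squares and
L-BFGS-B on the summed squares), best solution polished by a tighter
trust-region pass. Default bounds: `a ∈ [3·10⁻³, 2·10⁻²]`/d,
`m ∈ [10⁻⁹, 10⁻⁵]`, `μ0, μ*, χ ∈ [0, 1]`, `c50 ∈ [10¹⁴, 10¹⁸]`.
Standard errors are `sqrt(diag(H⁻¹))` of a central-difference Hessian of
the objective at the optimum; a non-positive-definite Hessian switches to a
pseudo-inverse and flags the errors as unreliable rather than reporting
them silently.

Chemotherapy and immunotherapy parameters are fitted jointly over the whole
history by default (the schedule structure already separates their eras in
time); nothing in the interface precludes era-wise fitting by fixing one
block.

## Synthetic patients

The generator emulates the clinical data situation: a diagnosis triggered
when the primary reaches a specified size, a therapy calendar (default:
four q3w chemotherapy cycles from diagnosis, then second-line antibody
dosing from day 90), and a handful of CT visits at which the *total* burden
is measured. Measurement noise is multiplicative lognormal (default
σ = 0.05), reflecting volumetry error that scales with volume; additive
noise would be inconsistent with burdens spanning decades. Visible-lesion lists are thresholded at a detection limit
(default 10⁸ cells = 0.1 ml); the generator reports them per visit, but the
fit consumes only the total burden. The primary size at diagnosis is passed
through exactly (it anchors the time axis), a simplification relative to
re-measuring it with noise.

What the generator does **not** emulate: CT imaging and CAD false
positives/negatives, inter-lesion growth heterogeneity, organ-specific
kinetics, dose toxicity. Passing recovery tests therefore demonstrate
identifiability under the model's own assumptions, not robustness to model
misspecification.

### Parameter-recovery study

The reproducible study (`metaburden.experiments.parameter_recovery`) draws
20 virtual patients Latin-hypercube-spread over the fitted clinical
magnitudes (`a ∈ [5.5, 9]·10⁻³`, `m ∈ [1, 4]·10⁻⁷` log-uniform,
`χ ∈ [0.05, 0.12]`), five visits at days 0/30/90/150/240 after diagnosis,
5 % noise. The cohort mimics first-line immunotherapy patients (antibody
from day 30, no chemotherapy era) and fits `(a, m, χ)` with `c50` fixed:
on five-point series `c50 ≪ c_st` is practically unidentifiable (the Hill
term saturates), and adding an unknown chemotherapy era introduces a sloppy
direction in which `μ0`, `a` and `m` trade off against each other —
exploratory runs with four free parameters roughly double the spread of the
`m` estimates. The study is a statement of identifiability limits under
realistic sparsity, not a best-case demonstration: medians, not maxima, are
the reported statistic, and individual patients can miss by more.

## Numerical and design choices, collected

- `Δt = 1 d` default step (daily concentration/therapy resolution);
  integrators are exact within steps wherever the dynamics are autonomous.
- Step-midpoint dating of newborn cohorts (second-order seeding).
- Detection limit `s_vis` defaults, when a dataset is attached, to that
  patient's minimum measured volume; otherwise it must be given.
- Histograms count tumors within the supplied bin edges only; spanning
  `[1, K]` makes them sum to the total count.
- Latin-hypercube sampling with `n = 1` returns range midpoints
  (deterministic single-spec convenience).
- The regimen-comparison helper reports percent change of metastatic mass
  at a horizon relative to a reference schedule. A doubled loading dose
  brings the first-cycle mean concentration within 5 % of `c_st` exactly
  when the cycle length is close to the half-life (true for pembrolizumab
  q3w and nivolumab q4w, not for nivolumab q2w); halving the dose halves
  the plateau while the relative approach to it is dose-independent.

## Known limitations

- Deterministic expectations only; no branching-process variability in
  seeding, hence no prediction intervals on tumor *counts*.
- Published diagnosed-tumor counts depend on an unstated counting
  threshold; the solver's total count includes every expected
  micrometastasis down to one cell and is therefore systematically larger
  than thresholded clinical counts.
- Single shared growth law; organ-specific metastatic classes would need
  parallel densities.
- The chemotherapy model ignores dose dependence of resistance emergence
  and any inter-application drug persistence.
- Body volume is folded into concentration units; absolute concentrations
  are comparable within, not across, patients.
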