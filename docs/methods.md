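# Methods

## Model structure

`t2dmsim` is a deterministic, population-level compartmental model of type 2
diabetes mellitus (T2DM). The state space is the product of sex {female,
male}, sixteen 5-year age bands (0–4 … 70–74, 75+), the joint status of three
binary risk factors (obesity, current smoking, physical inactivity), and
disease status. Every susceptible stratum is additionally split by
physical-activity (PA) intervention status; strata with T2DM carry no
intervention label (conversion to T2DM drops it), giving 2 × 16 × 8 × 3 = 768
compartments. Smoking is a binary current-smoker state with no former-smoker
memory. Counts are continuous person-totals; there is no migration and no
continuous-BMI dimension.

The flows are: entry into the youngest band (susceptible, risk-free);
aging between adjacent bands at 1/(band width) = 0.2/year (none out of 75+);
background mortality μ(s,a); per-factor acquisition η_k(s,a) and cessation
ρ_k(s,a) acting independently on the joint 8-state combination (correlation
between factors emerges dynamically only); T2DM incidence; excess mortality
ν(s,a) from T2DM strata; and PA recruitment from (susceptible, none) to
(susceptible, pa_active) restricted to ages 15–64. Incidence hazards compose
multiplicatively under risk-factor independence,
λ = λ₀(s,a)·RR_ob^o·RR_sm^k·RR_in^i·RR_pa^e, with indicator exponents.
The intensity ladder for RR_pa is 0.61 (vigorous), 0.66 (low), 0.68
(moderate), 0.74 (leisure-time), 0.85 (walking); participants never leave the
intervention stratum except by developing T2DM (no exit pathway is modelled).

Cumulative incident cases and excess deaths are co-integrated with the state
as integrals of the corresponding hazard flows, per (sex, age band). All
averted-burden measures are differences of these integrals against a
no-intervention counterfactual sharing the initial state and reporting grid;
prevalent-count differences are never used, so deaths and aging cannot
masquerade as prevention.

## Numerical integration

The default solver is scipy's adaptive explicit Runge–Kutta (RK45) with
rtol 1e-8 and atol 1e-10, reporting on a yearly grid over 2016–2050. A
fixed-step classical RK4 mode (default dt = 0.01 year) serves as an
independent oracle in the tests and, at dt = 0.25 year, as the integrator for
calibration residuals, where a fixed-step scheme keeps the objective smooth
in the parameters (adaptive step-size selection introduces tiny
discontinuities that pollute finite-difference Jacobians). Counts below
−1e-9 × the total population abort the run with the offending time and
compartment; smaller negatives are clamped to zero at reporting times only.
On an empty-flow system the integrator is exact; on the full system the
adaptive and RK4 solutions agree to better than 1e-10 relative over 5 years,
and total population is conserved to ~1e-15 relative over the full horizon
when mortality and entry are switched off.

## Scenario engine

A scenario declares, per targeted factor, a relative reduction F ∈ [0, 1] of
its aggregate 15–64 prevalence, scaled up linearly from 2016 to 2031 and held
to 2050 (defaults; the ramp window is configurable, and scale-up-duration
variants of 5–20 years are bundled). F = 0 is a "halt": because the baseline's
aggregate prevalence drifts upward as the population ages (age-specific
prevalence is constant), pinning the 2016 level is an active intervention.
The explicit PA intervention ramps coverage linearly to 25% of susceptible
adults by 2031 and maintains it.

The mechanism that enforces a target trajectory is a deadbeat feedback
controller, applied at the start of every control step (0.5 year): it
measures the current aggregate prevalence, estimates the demographic drift
from the instantaneous no-intervention derivative, and solves for scalar
multipliers on the susceptible population's acquisition and cessation hazards
(bounded in [0, 10]) that deliver the required net flow over the step.
Saturated multipliers emit a warning rather than failing silently. The
controller acts only on susceptible compartments in the targeted age bands;
by default the prevalence denominator is the whole targeted-age population
(matching population-level WHO-style targets), with a switch for
susceptible-only denominators. PA recruitment is solved the same way from the
coverage gap. Tracking error at reporting years is below 0.05 percentage
points in all bundled scenarios, against an acceptance bound of 0.2.

## Synthetic data

The generator emulates the study conditions, not any real microdata: a young
national population (median age ≈ 21) whose 15–64 total grows from 144,066
(2016) toward 221,627 (2050); 2016 aggregate prevalences of 41.4% obesity,
16.2% smoking, 46.0% physical inactivity; and 16.7% adult T2DM prevalence.
Age profiles are logistic curves (midpoint, steepness, female:male multiplier
per quantity) rescaled so the 15–64 aggregates match exactly; smoking is
heavily male-skewed (female:male 0.15), obesity and inactivity mildly
female-skewed. The 2016 pyramid decays exponentially in age (rate 0.03/year)
with a 50% thinning of the child bands, so the working-age population ages
monotonically as the bulge cohorts move up; the entry stream grows
exponentially at a rate solved so the demography-only projection hits the
2050 anchor (an error is raised if no rate in ±15%/year can). Background
mortality is Gompertz (6e-5·e^(0.082·age), males ×1.1).

Reference ("true") rates are constructed by a quasi-stationarity balance:
η_k and λ₀ are solved per (sex, band) so the 2016 age-specific prevalence
profiles are approximately invariant under aging inflow, cessation (ρ fixed
at 0.02/0.03/0.04 per year for obesity/smoking/inactivity), incidence, and
excess death — reproducing the baseline assumption of constant age-specific
risk-factor prevalence with aggregate drift driven purely by the pyramid.
Relative risks default to 4.3 (obesity, consistent with obesity explaining
roughly 60% of incidence at 41% prevalence), 1.37 (smoking), and 1.5
(inactivity). ν is Gompertz in age with its level solved so the 2016
case-fatality rate is 8.6 per 1000 prevalent cases per year. Under these
defaults the baseline projects 16.7% → 18.7% (2031) → 21.8% (2050) adult
prevalence, a monotone rise inside the intended 16–25% band; the dose–response
ordering across reduction levels and the dominance of obesity over smoking
and inactivity mirror the qualitative structure expected of this system.

The initial 2016 state fills risk-factor combinations by per-factor
independence within each (sex, band), with disease status independent of
factor status and all PA compartments empty. What passing tests on these data
do **not** show: goodness of fit to real survey microdata, behaviour under
factor correlations present at baseline, former-smoker residual risk, or
migration — none of which the generator emulates.

## Calibration

The fitted quantities are seven multiplicative family scales on a template
parameter set: λ₀ per sex, η per factor, ν, and the entry stream. Cessation
hazards stay at their priors because acquisition and cessation are only
jointly weakly identified by prevalence data. Because the 2016 initial state
is constructed from the 2016 targets, those rows carry no information about
the rates; identification comes from model-generated age-specific prevalence
targets at 2031 plus 15–64 population totals at 2016/2031/2050 (population
rows are weighted by inverse squared value to put them on the prevalence
scale). The optimiser is scipy's bounded trust-region least squares on
log-scales (bounds ×0.5–×2), finite-difference Jacobian with relative step
1e-4, optional seeded multi-start with log-uniform perturbed starts. A
solution pinned at a bound is reported as such and flagged not converged.
On noiseless self-generated targets the truth is recovered to ~1e-6 from
±20% perturbed starts; with 0.5-percentage-point target noise the weakest
family is ν (excess mortality barely moves prevalence), with a median
relative error around 10% across seeded replicates.

## Outcome conventions

Prevalence is cases/population over ages 15–64, both sexes, at a reporting
year. The case-fatality rate at year y is the cumulative-excess-death
increment over [y, y+1] divided by the mid-year prevalent count (average of
the bracketing grid points), ×1000, with deaths and cases taken over the same
age range. Relative prevalence reductions are computed on unrounded values;
reported percentages are rounded half-up to one decimal only at the
formatting layer. The suite report runs the baseline plus all 30 bundled
scenarios and emits one row each with 2031/2050 prevalence, relative
reductions, and cases/deaths averted over 2016–2031 and 2016–2050.

## Problem sizes and defaults used in the shipped runs

Tests and the acceptance script run the full 768-compartment system over
2016–2050 with the default solver; calibration experiments use RK4 at
dt = 0.25 year (dt = 0.5 in the 20-replicate noise study) over the same
horizon. The oracle comparisons use a 4-compartment constant-rate subsystem
against the matrix exponential and a 5-year full-system run against RK4 at
dt = 0.01 year.

## Known limitations

Exact reproduction of any particular published projection is out of scope:
the reference rates are synthetic stand-ins constructed from aggregate
anchors, not a fitted national parameterisation, so burden counts carry the
generator's assumptions. No uncertainty analysis is performed (point
projections only). The controller enforces aggregate — not per-band — target
trajectories; per-band prevalence under intervention follows from where the
multipliers act. Health-expenditure projections, T2DM complications, and
non-national resident populations are not modelled.
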