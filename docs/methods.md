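# Methods

`chemorad` models 1-year overall survival (OS) of locally advanced
unresectable pancreatic cancer (LAUPC) as a function of the biologically
effective dose (BED) of the radiotherapy course, with chemotherapy entering
as an independent additive survival contribution. This note records the
model, the conventions the package had to pin down where the published
record is silent, the numerical choices, and what the synthetic-data tests
do and do not demonstrate.

## The model

**BED.** A schedule of *n* fractions of *d* Gy delivered over *T* calendar
days is summarised by the linear-quadratic BED with a repopulation time
factor:

    BED = n d (1 + d/(α/β)) − ln 2 · (T − T_k)_+ / (α T_d)

with α = 0.393 Gy⁻¹, α/β = 6.77 Gy, tumour doubling time T_d = 42 d, and a
repopulation kick-off delay T_k (default 17 d; `(x)_+ = max(0, x)`). The
ratio α/β is stored as the conventionally rounded 6.77 Gy rather than
recomputed from α and β (0.393/0.058 = 6.776…), so that the fractionation
term matches the arithmetic of the reference analyses. Proton and carbon
doses are taken in Gy(RBE) (protons: fixed RBE 1.1; carbon doses as quoted
by the treating institution) and used numerically like Gy everywhere
downstream.

**Survival.** Radiotherapy-attributable survival is logistic in BED,
RS = 1/(1 + exp[4 γ₅₀ (1 − BED/D₅₀)]), where γ₅₀ is the normalized
dose-response gradient and D₅₀ the BED at 50% 1-year survival under
radiotherapy alone. Chemotherapy contributes an independent survival CS,
combined additively: OS = CS + RS(1 − CS). No synergy term is offered; the
additive model is an explicit assumption, consistent with in-vitro evidence
for charged particles and with chemotherapy frequently being adjuvant or
neo-adjuvant rather than strictly concomitant. Inverting the RS curve at
RS = CS defines the *chemo-equivalent BED*, the radiation-alone dose that
would match chemotherapy's survival contribution.

## Timing conventions

The published cohort tables never print overall treatment time, so the
package fixes a convention and applies it uniformly:

- X-rays and protons: 5 fractions/week on consecutive weekdays, so
  T = 7·⌊(n−1)/5⌋ + ((n−1) mod 5) + 1 (28 fractions → 38 d; 33 → 45 d).
- Carbon ions: the 12-fraction course is institutionally fixed at 3 weeks,
  so those schedules carry an explicit `overall_time_days = 21`.
- A schedule may always override the weekly rule with an explicit time.

**Kick-off delay.** The plain time-factor BED (T_k = 0) is inconsistent
with the published BED column: 28 × 1.8 Gy gives 63.8 Gy with no time
penalty and 62.2 Gy with the full 38-day penalty, while the published value
is 62.9 — implying ≈21 effective penalty days. A brute-force integer grid
search of T_k over 0–38 d against the five reference schedules whose times
the conventions above pin (62.9, 97.8, 65.2, 97.4, 92.5) has its optimum at
T_k = 17 d, reproducing all five within 0.1 Gy; that value is frozen as the
default and re-verified in the test suite. Setting `kickoff_delay_days=0`
recovers the plain formula. Two reference rows are *not* reproducible under
any single convention (the 25 Gy × 1 row prints 117.5 vs the closed-form
117.3; the 18-fraction carbon row implies ≈28 effective days); the package
reports its own values there and does not tune constants toward them.

## Data fixtures

The packaged CSV tables transcribe the published LAUPC cohort tables:
5 X-ray-alone cohorts, 18 X-ray+gemcitabine, 27 X-ray+other-drug arms
(multi-arm rows split, e.g. the two 1981 dose arms and the two 2013
TNFerade-trial arms), 10 X-ray+gemcitabine-cocktail, and 6 charged-particle
arms (two proton studies and four carbon-ion sub-groups). Conventions:

- Rows printing dose or fraction ranges use the midpoint schedule (fraction
  midpoints rounded half away from zero) and keep the printed bounds in
  `dose_low`/`dose_high` for reporting; the fit uses the midpoint only.
- Survivor counts are not printed anywhere; they are reconstructed as the
  nearest integer to `os1y_fraction × n_total` (ties half away from zero).
  An invariant enforces |n_s/n_tot − printed fraction| ≤ 0.5/n_tot on every
  row, so the reconstruction is unique.
- The two carbon-ion monotherapy arms are flagged `included_in_fit = false`
  (they are plotted in the source analysis but take part in no fit); every
  excluded row must carry an explicit reason.
- Files carry a `# cohort-csv v1` schema line; reading is strict (exact
  header, per-row diagnostics) and writing round-trips losslessly.

## Fitting

Published fractions carry a Poisson counting error, SD = √n_s / n_tot
(survivor count floored at 1 so a 0% cohort keeps finite weight). The
objective is weighted least squares on the proportion scale with weights
1/SD²; dose-range error bars are display-only and never enter the
objective. Three stages, each freezing what the previous stage estimated:

1. **X-rays alone** (5 cohorts): γ₅₀ and D₅₀ free.
2. **X-ray chemoradiation** (55 arms pooled; gemcitabine-only and
   other-drug subsets reported alongside): CS free, γ₅₀/D₅₀ frozen.
3. **Charged-particle chemoradiation** (4 arms): a particle D₅₀ in Gy(RBE)
   free, γ₅₀ and the pooled CS frozen. A lower particle D₅₀ at equal
   nominal BED quantifies benefits beyond the RBE bookkeeping (oxygen
   effect, dose conformity).

Optimisation is derivative-based least squares (trust-region reflective,
bounds γ₅₀, D₅₀ > 0 and 0 ≤ CS < 1) with five documented starting points,
iteration cap 500 and tolerance 1e−10; the start with the lowest weighted
RSS wins. One-parameter stages are cross-checked in the tests against a
1000-point grid-search oracle.

**Standard errors.** The covariance is the Jacobian Gauss–Newton covariance
(JᵀWJ)⁻¹ scaled by max(1, reduced χ²). The floor matters: the Poisson
weights are absolute counting errors, so the unscaled covariance is already
on an absolute scale; the χ² factor inflates it when the data are
overdispersed (the pooled chemoradiation fit has reduced χ² ≈ 2, reflecting
three decades of heterogeneous protocols) but is not allowed to *deflate*
it on the 3 residual degrees of freedom of stage 1, where a downward χ²
fluctuation would randomly shrink the reported errors. When the stages run
chained inside `run_full_protocol`, the covariance of the frozen upstream
parameters is propagated into the later stages' standard errors by the
delta method: the sensitivity of the one-parameter estimate to each frozen
value is measured by central finite differences (1% relative step,
re-solving the fit), and the propagated variance adds to the conditional
fit variance; the γ₅₀–CS covariance feeding stage 3 is assembled from the
stage-1 covariance and the stage-2 sensitivity. Without propagation the CS
interval is conditional on the stage-1 point estimates and undercovers
badly (≈66–71% at nominal 95% in simulation); with it, all four parameters
cover at 92–99%. Standalone fits against externally fixed parameter values
report the conditional (fit-only) error, which is also retained as
`stderr_fit` in chained results.

## Scenario prediction

`predict_scenarios` evaluates BED and expected OS for candidate schedules
under a named parameter set — by default the published fitted curves,
γ₅₀ = 1.2, CS = 0.36, D₅₀ = 107 Gy (X-ray) or 75 Gy(RBE) (particles). The
reference escalation table reproduces the published BED column for the five
pinned rows within 0.1 Gy and the escalated X-ray row's 61% survival
exactly. The charged-particle survival column of the published table is
*not* reproducible from the rounded published parameters (e.g. the proton
row evaluates to 88% vs a printed 75%); the unrounded parameters behind
those printed values are unrecoverable, so particle rows carry a
`model_output_diverges` flag and are reported as this model's own output.
Display percentages round half up; full precision is kept in the frame.
`os_doubling_bed` inverts the OS curve at twice a reference survival
(attainable range (CS, 1)), the quantity behind "dose needed to double
survival" planning arguments.

## Synthetic data and what the tests show

The simulator draws virtual cohorts under the package's own assumptions:
p = OS(BED) from the generating curves, survivor count ~ Binomial(n_tot, p),
OS fraction = count/n_tot. The mirrored design copies the real fixture
layout exactly (same 64 schedules, cohort sizes and chemotherapy
categories; generating values γ₅₀ = 1.2, D₅₀ = 107 Gy, CS = 0.36, particle
D₅₀ = 75 Gy(RBE)). The generator uses exact binomial noise while the fit
uses the Poisson SD approximation — deliberately, since that is the
approximation applied to the real tables; the calibration tests measure its
impact. Sub-seeds derive from (seed, replicate, arm index) via
`SeedSequence` spawn keys, so output is reproducible byte-for-byte and
invariant to arm ordering.

With 200 replicates the full protocol recovers each generating parameter
within 2 SE in ≥ 90% of replicates, and 95% intervals for (γ₅₀, D₅₀, CS)
cover within [0.85, 0.99]. This validates the estimation machinery *under
the model's own sampling assumptions only*: real cohorts differ by
institution, era, staging, chemotherapy protocol and reporting conventions,
none of which the binomial generator emulates, and the real-data reduced
χ² ≈ 2 shows exactly that overdispersion. Passing recovery tests therefore
says the pipeline is correct and calibrated, not that the model is true.

## Numerical choices and degenerate inputs

- Logistic evaluation uses `scipy.special.expit` (RS) and an exponent clip
  at ±700 (closed-form OS) so extreme BEDs saturate instead of overflowing;
  the two OS routes agree to < 1e−12 over the tested grid.
- Stage 1 refuses < 3 cohorts (under-determined); one-parameter stages
  refuse empty selections. Fits with zero residual degrees of freedom skip
  the χ² scale (factor 1).
- Cohort order does not affect estimates beyond optimiser tolerance
  (summation order), verified to 1e−6 relative.
- `derive_survivor_count` and display-percent rounding both round ties half
  away from zero / half up, matching how the printed percentages behave.

## Problem sizes

All real-data fits are desk-scale (≤ 55 points, ≤ 2 free parameters) and run
in milliseconds. The recovery study uses 200 replicates × 64 arms and
completes in well under a minute; the examples use 50 replicates for a
quicker narrative run.

## Known limitations

- 2-year OS and median OS are stored in the fixtures but deliberately
  unmodelled; the endpoint is the 1-year binary outcome, with no censoring.
- Carbon-ion Gy(RBE) values are taken as printed; no microdosimetric or
  local-effect RBE model is applied, so cross-institution carbon doses are
  only as comparable as their quoted RBE systems.
- The treatment-time convention is an inference (the sources never print
  T); all fitted parameters are conditional on it, which is why acceptance
  tolerances for the fits are the published ± ranges rather than equality.
- Chemotherapy is a category, not a dose: CS summarises heterogeneous drugs
  and sequencing into one number per subset.
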