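# Methods

`attrecho` re-implements, as a reusable and tested package, the statistical
machinery of a 30-month, two-arm, placebo-controlled echocardiographic
endpoint analysis in transthyretin amyloidosis with cardiomyopathy
(ATTR-CM): derivation of echo parameters from raw measurements, a mixed
model for repeated measures (MMRM) of change from baseline with
unstructured covariance, and a four-pattern pattern-mixture
multiple-imputation (MI) sensitivity analysis pooled by Rubin's rules.
Individual patient data from such trials are access-restricted, so the
package ships a synthetic-trial generator that emulates the study's data
structure with known ground truth; every statistical claim the test suite
makes is made against that generator or against closed-form oracles.

## Echo parameter derivation

Derived quantities follow the standard American Society of Echocardiography
conventions:

* mean LV wall thickness = (IVSd + PWd) / 2, in mm;
* relative wall thickness = 2·PWd / LVEDD;
* LV mass (g) by the Devereux linear-dimension formula
  0.8·1.04·((IVSd + LVIDd + PWd)³ − LVIDd³) + 0.6 with inputs in cm,
  indexed to body surface area (Du Bois by default, Mosteller available);
* LV volumes by the modified biplane Simpson method of discs,
  V = (π/4)·Σᵢ aᵢbᵢ·(L/20) over 20 paired disc diameters;
  LVEF = 100·(EDV − ESV)/EDV;
* LVOT stroke volume = π·(d/2)²·VTI;
* E/A and E/e′ ratios, with the *average* E/e′ computed as E divided by the
  mean of the lateral and septal e′ velocities (the averaging convention is
  not universal; it is the one adopted here);
* global longitudinal strain is accepted as a supplied signed value and
  stored as its absolute magnitude (`abs_gls`).

Each registry entry carries units and a **worse direction** — whether an
increase or a decrease in the change from baseline is clinically adverse.
Wall thickness, LV mass index, chamber sizes, E/e′, E/A, TR velocity and
IVC diameter worsen upward; LVEF, absolute GLS, stroke volume and the
annular tissue velocities (e′, a′, s′, RV S′) and A wave worsen downward.
The registry is the package's clinical interpretation and is configurable;
it only affects the worst-decile imputation of Pattern 1.

## Synthetic trial generator

One echo parameter per run. Each patient receives a baseline value
N(μ₀, σ₀²) and a 4-vector of changes from baseline at months 12/18/24/30
drawn from a multivariate normal with an arm-specific mean profile, an
unstructured 4×4 within-subject covariance, a regression-to-the-mean term
in the baseline deviation, and small additive stratum effects. Default
conditions emulate the target cohort:

* 327 patients per arm; ~40% baseline tafamidis users; 88% wild-type ATTR;
  ~55% aged ≥75; 9% NYHA III; 27% NT-proBNP >3,000 ng l⁻¹;
* stroke-volume-scale outcome: baseline 52 (SD 17.5) ml; placebo profile
  (−1.6, −3.3, −4.9, −6.5) ml, active profile (−0.6, −1.2, −1.8, −2.4) ml —
  a true month-30 effect of +4.1 ml; within-subject SDs (9, 10.5, 12, 13.5)
  with AR-like correlation 0.7^|i−j|;
* deaths and treatment discontinuations from independent per-day
  exponential hazards (1.1×10⁻⁴ and 2.5×10⁻⁴, i.e. roughly 10% deaths and
  20% discontinuations by month 30); the last dose day is the last
  84-day-interval dose before end of dosing;
* missingness: visits at/after the death day are always missing;
  off-treatment visits (>126 days after last dose) of discontinued patients
  are missing with probability 0.5, so retrieved dropouts exist; on top of
  that MCAR coin flips, MAR monotone dropout with a per-visit hazard
  logistic in the previous visit's observed change, or MNAR deletion
  logistic in the value being deleted. Defaults produce ≈34% missingness at
  month 30, matching the analyzed fractions of the emulated study.

Visit days are fixed at 0/365/548/730/913 (needed for 126-day-window
arithmetic); there are no visit windows around nominal days. Death,
transplant and LV assist device placement are a single `death_day` field
because the imputation treats them identically. What the generator does
*not* emulate: correlated multi-parameter panels, site or sonographer
effects, measurement rounding, visit-time jitter, or informative death —
passing tests demonstrate correctness of the estimators under the stated
data-generating law, not robustness to every feature of real trial data.

## MMRM

The response is the change from baseline at the four post-baseline visits;
baseline change is identically zero and the baseline value enters as a
covariate, so baseline is not modeled as a response visit. Fixed effects:
arm-by-visit cell means (equivalently treatment, visit and their
interaction; a reference coding is available), baseline value, ATTR
genotype and age group; the overall population adds baseline tafamidis use
and its interaction with treatment, both dropped in the monotherapy and
tafamidis-subgroup populations where the factor is constant. Patients
contribute the submatrix of the shared unstructured covariance matching
their observed visits — incomplete cases are used without imputation,
which is valid under MAR.

Estimation is REML with the fixed effects profiled out by generalized
least squares. The covariance is parameterized by the log-Cholesky factor
(10 free parameters for 4 visits) and maximized by L-BFGS with analytic
gradients; starting values are the pairwise-complete covariance of OLS
residuals floored to positive definiteness at 1e-6 of the largest
eigenvalue. Convergence requires a relative objective change below 1e-13
(optimizer ftol) or a projected-gradient norm below 1e-6; subjects are
grouped by missingness mask so each likelihood evaluation costs a handful
of ≤4×4 factorizations.

LS means weight classification-factor levels equally and fix the baseline
covariate at its analysis-set mean; the treatment difference is active
minus placebo. Degrees of freedom are Satterthwaite by default (the
variance of the covariance parameters is the inverse observed REML
information, obtained by finite differences of the analytic score), with
residual df available as an option. Inference is two-sided at α = 0.05
with no multiplicity adjustment.

## Pattern-mixture imputation

Missing post-baseline cells are classified with a 126-day window
(1.5 × the 84-day dosing interval):

1. **Death before the month-30 visit** — worst-decile sampling: donors are
   observed changes at the same visit, arm and tafamidis group; the worst
   ⌈0.1·n⌉ values (at least one donor; the spec of the rounding is the
   package's choice) form the sampling set, drawn uniformly with
   replacement. An empty stratified pool falls back to the arm-level pool.
   By default Pattern 1 covers the decedent's visits at/after the death
   day; a flag extends it to all of the decedent's missing visits.
2. **Active arm, missing on treatment** (≤126 days after last dose) — MAR
   MI by multivariate-normal data augmentation, estimated from active-arm
   patients' on-treatment observations in the same tafamidis group.
3. **Active arm, missing off treatment** — (i) with ≥10 retrieved dropouts
   at month 30 in the stratum, Bayesian normal-regression imputation
   estimated solely on the retrieved dropouts' off-treatment observations
   at the target visit (falling back to intercept+baseline, then
   intercept, on singular designs); (ii) otherwise copy reference.
4. **Placebo arm** — on-treatment gaps are MAR MI from all placebo
   patients in the stratum; off-treatment gaps use retrieved dropouts when
   sufficient, MAR MI otherwise.

The MCMC imputation model regresses the 4-vector of changes on ATTR
genotype, NYHA class, age group, NT-proBNP group and the baseline value,
separately by arm and tafamidis group. Data augmentation alternates an
I-step (missing cells from their conditional normal) and a P-step (the
coefficient matrix and covariance from the conjugate
matrix-normal/inverse-Wishart posterior under a Jeffreys prior); the chain
burns in 500 iterations and retains one draw every 100 iterations, one
retained draw per imputation index. Nonmonotone gaps need no special
handling. Copy reference takes the patient's entire joint outcome law
from the placebo arm of the same tafamidis group: reference parameters are
a fresh posterior draw per imputation index (so Rubin variance is proper),
and the missing cells are drawn conditionally on the patient's observed
post-baseline changes and covariates, following the Carpenter–Kenward
copy-reference construction. Conditioning uses actually observed values
only, never values imputed by another pattern.

Every imputed change, from any method, is capped below at 0 − baseline, so
an imputed post-baseline value never goes negative. For parameters whose
worse direction is upward the cap is literal and never binds. m = 100
completed datasets by default; per-cell provenance (pattern, method, donor
pool size) is recorded.

## Pooled analysis

Each completed dataset gets an ANCOVA of month-30 change on baseline,
treatment, tafamidis use, treatment-by-tafamidis, ATTR genotype and age
group (tafamidis terms dropped outside the overall population); the
estimate is the LS-mean treatment difference with the same equal-weights
convention as the MMRM. Rubin's rules combine the m estimates:
q̄ = mean(qᵢ), ū = mean(seᵢ²), b = Σ(qᵢ−q̄)²/(m−1), T = ū + (1+1/m)·b,
with Barnard–Rubin degrees of freedom using the ANCOVA residual df as the
complete-data df, and t-based CI and p-value.

## Numerical choices and degenerate inputs

* Non-positive-definite covariance inputs are rejected at configuration;
  internally, near-singular conditional covariances are floored at 1e-8 of
  the largest eigenvalue (only ever reached in degenerate fixtures).
* A zero Doppler denominator flags that ratio missing rather than aborting
  the record; a missing baseline excludes the patient from that
  parameter's analysis set.
* Rank-deficient designs abort naming the aliased columns; structurally
  empty columns (an unpopulated level) are dropped instead.
* All randomness flows through `numpy` Generators seeded from the run
  seed; distinct pipeline stages and imputation indices use distinct fixed
  stream offsets, so runs are bit-reproducible and imputation indices are
  mutually independent.

## Simulation sizes used by the test suite

The statistical acceptance tests run: the REML closed-form oracle at
n = 40; type-I error at n = 100/arm over 1,000 replicates (band
[0.037, 0.065]); parameter recovery and CI coverage at n = 300/arm over
500 replicates; MI calibration at n = 200/arm, ~30% monotone MAR dropout,
m = 20 over 200 replicates (MC chains scaled to 100 burn-in / thin 10 for
the replicated study); and the copy-reference direction check at
n = 300/arm with 15% and 30% active-arm dropout. These sizes are the
package's Monte-Carlo design choices; all pass on a single CPU in a few
minutes.

## Known limitations

* Degrees-of-freedom options are Satterthwaite or residual; Kenward-Roger
  is not implemented.
* No jump-to-reference or delta-adjustment (tipping-point) variants; no
  imputation of baseline values; no GEE or random-slopes alternatives.
* One parameter per dataset; cross-parameter correlation is out of scope.
* The retrieved-dropout imputer is a per-visit Bayesian regression on the
  retrieved set — the simplest construction consistent with anchoring
  off-treatment imputation on retrieved dropouts.
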