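# Methods

This note records the statistical and economic model the package
implements, the choices made where the design was genuinely open, and what
the synthetic data do and do not demonstrate.

## Study design being analysed

The pipeline targets a two-arm, individually randomised, multi-site ICU
trial of a rapid in-ICU syndromic PCR panel versus standard of care in
HAP/VAP, with two binary co-primary outcomes — antibiotic stewardship at
24 h (on active *and* proportionate antibiotics) and clinical cure of
pneumonia at 14 days — and patient-level NHS costs. Analyses are
intention-to-treat and complete-case: records missing the scenario's
outcome or without a resolvable ICU cost are excluded and counted, never
imputed.

## Costing

**Cost sources.** ICU costs come from hospital finance departments
(income as a proxy for cost, covering the contiguous ICU stay from
randomisation) with trial-collected ICU days — censored at day 21 — as
the fallback, valued at a configurable daily rate. The merge rule is
strict priority: trial-collected days are never used when a finance cost
exists. The daily rate defaults to £2,000/day (a mid-range NHS adult
critical-care unit cost); it is configuration, not a derived quantity.

**Base case and total costs.** Base-case cost = ICU stay cost from
randomisation + panel cost (intervention only, `tests × per-test cost`).
Routine diagnostics and antibiotics are costed for reporting but not
added to the base case, because the ICU income already embeds them
(double-counting exclusion). "Total" cost replaces the contiguous stay
with the whole-admission income (all ICU stays plus general wards) and is
only defined for participants with whole-admission finance data, so its N
is smaller.

**Device annuitization.** The instrument is annuitized over a 5-year life
at 3.5% interest with no resale value:
`EAC = (price − resale·(1+r)^−L)/A(r, L)` with
`A(r, L) = (1 − (1+r)^−L)/r` (computed via `expm1`/`log1p` so the r → 0
limit, `A = L`, is reached continuously). Cost per test spreads the EAC
(or an annual leasing cost) over 360 tests/year and adds consumables, QC
and five minutes of band-6 nurse time. The published per-test figure of
£196 rests on confidential price quotes, so £196 is a configuration
default for downstream analyses and the packaged device config is an
explicitly synthetic decomposition.

**Discounting.** Costs accruing within one year of randomisation are
taken at face value; beyond that the excess horizon is discounted at
annual compounding, `cost·(1+r)^−(t−1)` — a conventional choice, and
immaterial for the ≤1-year stays that dominate ICU data.

**Antibiotics.** Acquisition costs only. Administrations per course =
frequency/day × whole days with partial final days rounded up, minimum
one administration (a course recorded with start = end reflects at least
one dose). Courses whose (drug, dose, route) is absent from the price
table are *reported* as unpriced, never silently zero-costed.

**Censoring and outliers.** The 14-day cost-censoring scenario converts
each stay's lump-sum cost to a uniform daily rate over the contiguous
stay (whole days, half-open interval, minimum 1 day to avoid
zero-division on same-day discharge) and keeps the first 14 days; stay
lengths are truncated alongside so the operation is idempotent. The
outlier scenario drops stays costing strictly more than £200,000.
Censoring is defined for base-case ICU costs only; a whole-admission lump
sum has no per-day decomposition, so requesting it on a total-cost
dataset is an error.

## Estimation

Treatment effects adjust for site at minimum. Costs use a linear mixed
model with a site random intercept (REML); if the variance component is
degenerate (zero or non-converged) the fit falls back deterministically
to OLS with site fixed effects and is flagged — with 14 sites the two are
near-identical, and a deterministic path keeps bootstrap replicates
well-defined. Binary outcomes use a variational-Bayes logistic mixed
model with the analogous fixed-effects fallback; no frequentist GLMM
exists in the supported Python stack, and the parameter-recovery tests
against the generator define the estimator contract. A single-site
dataset is fitted as a plain logit (for costs it is an error directing to
the unadjusted comparison).

Odds ratios are converted to the risk-difference scale by marginal
standardization: mean predicted probability with all records set to
intervention minus all set to control, random intercepts at zero
(fixed-effect site terms at their observed values). On a saturated
single-site model this reproduces the raw proportion difference exactly —
a property used as an oracle test. Unadjusted cost comparisons use Welch
normal-approximation 95% CIs with Satterthwaite degrees of freedom.

Subgroup analyses (adult/paediatric, covid status, HAP/VAP) add
arm-by-subgroup interactions on site-fixed-effects models and report
per-level cost differences and odds ratios; levels with an empty arm cell
are skipped with a warning, and a single-level subgroup degenerates to
the main effect.

## Bootstrap and decision metrics

Uncertainty is characterised by non-parametric bootstrap, default
B = 1,000, resampling participants with replacement *stratified by arm*
(arm sizes fixed); site structure is preserved through the refitted site
terms rather than a cluster bootstrap (a cluster bootstrap of 14 sites
would be dominated by a handful of site draws). Replicates refit the
site-fixed-effects models — fast and deterministic; whether to refit the
full mixed models per replicate is an open question in this literature,
and the replicate model choice is pinned here by synthetic-data recovery,
not by matching any specific dataset. Replicate r draws from a generator
seeded by (scenario seed, r), so every replicate is independently
reproducible. Non-converged or separated replicates are dropped and
counted; more than 20% dropped raises a hard diagnostic error.

Conventions (chosen and documented, since boundary behaviour is rarely
stated in applied work): quadrant shares classify (ΔC, ΔE) with SE =
(ΔC<0, ΔE>0), NE = (ΔC≥0, ΔE>0), SW = (ΔC<0, ΔE≤0), NW = (ΔC≥0, ΔE≤0),
so the origin counts NW and shares sum to one exactly; a net monetary
benefit of exactly zero counts as not cost-effective; ΔE = 0 yields an
undefined ICER. CEACs default to a willingness-to-pay grid of £0–£10,000
in £100 steps per one-percentage-point effect gain (the proportion-scale
ΔE is multiplied by 100 before applying λ).

## Synthetic trial generator

The generator's defaults are the study conditions: n = 530 participants,
14 sites (3 paediatric), 1:1 allocation; stewardship baseline 0.559 with
arm odds ratio 2.51; cure baseline 0.645 with arm odds ratio 0.689;
pooled 28-day mortality 0.30; ICU costs gamma distributed per arm with
(mean, SD) = (£40,951, £53,658) control and (£32,951, £36,989)
intervention; 11.5% of participants missing finance data (falling back to
day-21-censored trial days); every intervention participant tested once
with repeat probability 0.0102, so the mean per-person panel cost is £198
at £196/test.

Structure: outcomes follow logistic models with additive site random
intercepts on the logit scale; costs multiply a moment-matched gamma
quantile by a mean-one lognormal site effect. A gamma marginal (rather
than lognormal) reproduces the published SD > mean control arm with heavy
right skew and is documented as swappable. Stewardship, cure, death and
the cost quantile share a Gaussian copula (defaults: stewardship–cure
0.2, cure–death −0.5, cure–cost −0.2) so cost-by-outcome splits are
non-degenerate; whole-admission income is comonotone with the ICU cost.
Site SDs default to 0.2 on both scales — the motivating trial reports no
between-site variance, so these are assumptions, flagged in the config
docs. Covariates (VAP fraction 0.6, covid yes/unknown 0.15/0.05, SOFA ~
Poisson(6), other infection 0.25) are plausible ICU values chosen once;
they carry no generating effect on costs or outcomes unless configured.
Optional arm-by-infection-type shifts let subgroup recovery tests build
in opposite-sign cost effects.

**What passing tests do not show.** The generator reproduces arm-level
moments and effect sizes, not patient-level ICU dynamics. In particular,
with per-arm gamma stays moment-matched to the published mean/SD, the
*generating* 14-day-censored cost difference is slightly positive
(closed-form E[min(S, 14)] ≈ 8.68 vs 8.87 days): the control arm's
heavier skew puts more of its mass at short stays. Real data from such a
trial can instead show a negative censored difference, i.e. separation in
the first 14 days that second-moment calibration cannot encode. Scenario
tests therefore assert signs only where the generating truth implies
them, and the censored scenario's sign is not asserted. Calendar dates,
antibiotic prescribing patterns and within-stay cost profiles are
synthetic conveniences, not emulations.

## Problem sizes and tolerances

Moment-convergence checks run one 200,000-participant draw (±0.5 pp on
proportions, ±1%/±2% on cost mean/SD); parameter recovery uses
5,000–10,000 participants with 3×SE tolerances; Welch-interval coverage
uses 500 trials of n = 530 against a closed-form censored-gamma oracle
for the resolved-cost estimand, asserting 93–97% empirical coverage;
scenario-suite and bootstrap tests use the trial scale (n = 530) with
B = 100–200, and the acceptance script uses B = 1,000 at trial scale.
These sizes keep every check a Monte-Carlo-stable assertion rather than a
flaky one.

## Known limitations

* Income-as-cost is inherited from the data-collection design; no
  inflation adjustment beyond the 2020/21 price year is implemented.
* No QALY analysis (the trial design precluded quality-of-life
  collection) and no value-of-information analysis.
* The variational-Bayes mixed logit gives approximate posteriors; its
  point estimates agree with the fixed-effects fit to well within
  sampling error at the trial scale, and all bootstrap inference uses the
  fixed-effects path.
* Multiple non-contiguous ICU stays are handled only through the
  whole-admission income in the total-cost scenario.
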