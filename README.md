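# icucea

Within-trial cost-effectiveness analysis of rapid, in-ICU syndromic PCR
testing for hospital-acquired and ventilator-associated pneumonia
(HAP/VAP), from the perspective of NHS secondary care.

HAP/VAP patients conventionally receive broad-spectrum empiric antibiotics
that are refined after 48–72 h once routine microbiology reports. A rapid
syndromic PCR panel run inside the ICU returns results in about 1.5 h and
may improve antibiotic stewardship — but it costs money, and its value
depends on what happens to ICU costs and clinical outcomes. `icucea`
implements the full within-trial economic evaluation of such a device
against standard of care in a two-arm, multi-site individually randomised
trial, for health economists and trialists who want a reusable, testable
pipeline rather than a one-off analysis script:

* **Micro-costing** — equivalent annual cost (EAC) annuitization of the
  instrument, cost per test and per person (including repeat tests after
  failures), unit-costed resource use (cultures, viral PCR, X-ray, CT),
  antibiotic acquisition costs, discounting of costs beyond one year.
* **Cost-source merging** — finance-department ICU income is preferred;
  where absent, day-21-censored trial-collected stays are valued at a
  configurable daily rate, with provenance flags and auditable exclusions.
* **Site-adjusted estimation** — linear mixed models for costs and
  logistic mixed models for the binary co-primary outcomes (antibiotic
  stewardship at 24 h; clinical cure at 14 days), each with a
  deterministic site-fixed-effects fallback, plus marginal
  standardization from odds ratios to risk differences.
* **Bootstrap cost-effectiveness analysis** — non-parametric bootstrap
  (Δcost, Δeffect) clouds, cost-effectiveness plane quadrant shares,
  ICER/dominance classification, and cost-effectiveness acceptability
  curves (CEACs), with a scenario suite covering the base case and the
  standard sensitivity analyses (finance-data-only, 14-day censoring,
  £200,000 outlier exclusion, covariate adjustment, total hospital costs)
  and subgroup interactions.
* **Synthetic trial generator** — a seeded simulator whose defaults
  reproduce the published arm-level summaries of the motivating trial
  (~530 participants, 14 sites, right-skewed ICU costs of ≈£41k vs ≈£33k,
  stewardship ≈56% vs ≈76%, cure ≈64% vs ≈57%, 28-day mortality ≈30%),
  since the patient-level data are not public.

## The model

For each scenario the incremental cost ΔC and incremental effect ΔE
(difference in outcome proportions, intervention − control) are estimated
from site-adjusted regressions. Joint uncertainty comes from bootstrap
resampling (B = 1,000, stratified by arm). Decision metrics follow the
standard within-trial framework:

* **ICER** = ΔC/ΔE, the extra cost per additional unit of effect, reported
  only when one strategy is not dominant;
* **dominance**: ΔC < 0 and ΔE > 0 means the intervention is cheaper and
  more effective (south-east quadrant of the CE plane) and no ratio is
  reported;
* **CEAC**: for willingness-to-pay λ (per one-percentage-point effect
  gain), the probability that the incremental net monetary benefit
  λ·(100·ΔE) − ΔC is positive across bootstrap draws.

Equipment is annuitized as EAC = price / A(r, L) with
A(r, L) = (1 − (1+r)^−L)/r, using a 5-year life and r = 3.5%.

## Worked example

```python
from icucea import SimulationConfig, generate_trial
from icucea.cea import ScenarioSpec, run_scenario

records = generate_trial(SimulationConfig(n_participants=530, seed=7))
res = run_scenario(
    records,
    ScenarioSpec(name="base_case", outcome="stewardship",
                 n_bootstrap=1000, seed=11),
    per_day_icu_cost=2000.0,
)
print(f"N = {res.n_control} control / {res.n_intervention} intervention")
print(f"Adjusted cost difference: £{res.cost_diff.point:,.0f} "
      f"(95% CI £{res.cost_diff.ci_low:,.0f} to £{res.cost_diff.ci_high:,.0f})")
print(f"Stewardship odds ratio: {res.odds_ratio.point:.2f}; "
      f"risk difference: {res.risk_diff.point:.2f}")
print(f"SE-quadrant share: {res.quadrants['SE']:.0%}; "
      f"interpretation: {res.interpretation}")
```

prints

```
N = 254 control / 276 intervention
Adjusted cost difference: £-6,073 (95% CI £-14,841 to £2,326)
Stewardship odds ratio: 2.50; risk difference: 0.19
SE-quadrant share: 93%; interpretation: Intervention preferred
```

i.e. on this synthetic trial the PCR-guided arm is estimated to cost
£6,073 less per patient (the bootstrap CI crosses zero), to improve the
odds of good stewardship 2.5-fold (a 19-percentage-point absolute gain),
and 93% of bootstrap draws land in the cheaper-and-more-effective
quadrant, so the intervention is the preferred strategy.

The same pipeline is available from the shell:

```bash
icucea simulate --seed 3 --out trial.csv
icucea cost --participants trial.csv --out costed.csv --summary-out table1.csv
icucea evaluate --participants trial.csv --seed 3 --out-dir results/
icucea report --evaluate-dir results/ --out-dir figures/
```

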