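"""Seeded generator of synthetic two-arm ICU trials.

Individual patient data from the emulated trial are not public, so every
downstream stage (costing, estimation, bootstrap cost-effectiveness) is
exercised on synthetic trials whose *defaults reproduce the published
arm-level summaries* (see :mod:`icucea.calibration`): ~530 participants
across 14 sites allocated 1:1, heavily right-skewed ICU costs with means of
roughly £41k (control) and £33k (intervention), stewardship success around
56 % vs 76 %, clinical cure around 64 % vs 57 %, pooled 28-day mortality
near 30 %, and ~11.5 % of participants lacking finance-department cost data
(falling back to day-21-censored trial-collected stays).

Generating model
----------------
* Binary outcomes follow a logistic model: logit(p) = logit(control
  baseline) + log(arm odds ratio) * arm + site random intercept.
* ICU costs are gamma distributed per arm, with shape/scale moment-matched
  to the target (mean, SD), multiplied by a lognormal site effect
  exp(u_site - sd^2/2) with mean one.
* Stewardship, cure, death and the cost quantile share a Gaussian copula so
  that cost-by-outcome splits are non-degenerate; whole-admission
  (general ward) income is comonotone with the ICU cost.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import gamma as _gamma
from scipy.stats import norm as _norm

from . import calibration
from .trial_data import (
    TRIAL_COLLECTION_CENSOR_DAY,
    AntibioticCourse,
    ParticipantRecord,
    ResourceUse,
    ValidationError,
)

_BASE_DATE = _dt.date(2019, 8, 5)

#: Synthetic antibiotic formulary used by the generator: (drug, dose, route)
#: with per-administration acquisition prices broadly in line with UK
#: hospital prices; purely illustrative.
SYNTHETIC_FORMULARY: list[tuple[str, str, str, float]] = [
    ("meropenem", "1g", "intravenous", 12.00),
    ("piperacillin-tazobactam", "4.5g", "intravenous", 7.50),
    ("vancomycin", "1g", "intravenous", 5.00),
    ("ciprofloxacin", "400mg", "intravenous", 9.00),
    ("co-amoxiclav", "1.2g", "intravenous", 1.80),
    ("linezolid", "600mg", "oral", 2.50),
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic trial.

    Defaults are calibrated to the published arm summaries; effect sizes are
    the site-adjusted odds ratios (stewardship 2.51, cure 0.689) and the
    Table-1 cost moments. Between-site SDs default to 0.2 (no published
    intra-class correlation exists; see the methods note).
    """

    n_participants: int = 530
    n_sites: int = 14
    allocation: float = 0.5
    site_sd_logit: float = 0.2
    site_sd_logcost: float = 0.2
    control_stewardship_p: float = 0.559
    intervention_stewardship_or: float = calibration.STEWARDSHIP_ODDS_RATIO
    control_cure_p: float = 0.645
    intervention_cure_or: float = calibration.CURE_ODDS_RATIO
    control_cost_mean: float = 40951.0
    control_cost_sd: float = 53658.0
    intervention_cost_mean: float = 32951.0
    intervention_cost_sd: float = 36989.0
    mortality_28d_p: float = 0.30
    finance_missing_p: float = 0.115
    # Whole-admission (general ward) income on top of the contiguous ICU
    # stay; means back-derived from the published total-cost summaries.
    control_general_cost_mean: float = 35047.0
    control_general_cost_sd: float = 40000.0
    intervention_general_cost_mean: float = 31310.0
    intervention_general_cost_sd: float = 30000.0
    total_extra_missing_p: float = 0.076
    # Routine diagnostic counts (Poisson rates per participant).
    culture_rate: float = 3.5
    viral_pcr_rate: float = 0.4
    xray_rate: float = 4.0
    ct_rate: float = 0.29
    # Baseline covariates.
    paediatric_fraction: float = 3.0 / 14.0  # fraction of sites that are paediatric
    vap_fraction: float = 0.6
    covid_yes_p: float = 0.15
    covid_unknown_p: float = 0.05
    sofa_mean: float = 6.0
    other_infection_p: float = 0.25
    # Panel testing: every intervention participant is tested once, with a
    # small probability of one repeat after a failed run (mean per-person
    # cost £198 at £196 per test).
    panel_repeat_p: float = 0.0102
    per_day_icu_cost: float = 2000.0
    # Optional arm-by-infection-type cost interaction: added to the
    # intervention-arm ICU cost mean for the named subgroup.
    hap_intervention_cost_shift: float = 0.0
    vap_intervention_cost_shift: float = 0.0
    # Gaussian-copula correlations between the latent drivers of
    # stewardship, cure, death and the cost quantile.
    corr_stew_cure: float = 0.2
    corr_stew_death: float = -0.1
    corr_cure_death: float = -0.5
    corr_stew_cost: float = 0.0
    corr_cure_cost: float = -0.2
    corr_death_cost: float = 0.0
    generate_antibiotics: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2 or self.n_sites < 1:
            raise ValidationError("need at least 2 participants and 1 site")
        for name in ("allocation", "control_stewardship_p", "control_cure_p",
                     "mortality_28d_p", "finance_missing_p",
                     "total_extra_missing_p", "vap_fraction",
                     "paediatric_fraction", "covid_yes_p", "covid_unknown_p",
                     "panel_repeat_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        for name in ("control_cost_mean", "control_cost_sd",
                     "intervention_cost_mean", "intervention_cost_sd",
                     "control_general_cost_mean", "control_general_cost_sd",
                     "intervention_general_cost_mean",
                     "intervention_general_cost_sd", "per_day_icu_cost"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive (gamma moment "
                                      "matching needs mean > 0 and SD > 0)")
        if self.intervention_stewardship_or <= 0 or self.intervention_cure_or <= 0:
            raise ValidationError("odds ratios must be positive")
        if self.site_sd_logit < 0 or self.site_sd_logcost < 0:
            raise ValidationError("site SDs must be >= 0")

    def copula(self) -> np.ndarray:
        """Latent correlation matrix (stewardship, cure, death, cost)."""
        r = np.array([
            [1.0, self.corr_stew_cure, self.corr_stew_death, self.corr_stew_cost],
            [self.corr_stew_cure, 1.0, self.corr_cure_death, self.corr_cure_cost],
            [self.corr_stew_death, self.corr_cure_death, 1.0, self.corr_death_cost],
            [self.corr_stew_cost, self.corr_cure_cost, self.corr_death_cost, 1.0],
        ])
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise ValidationError("copula correlation matrix is not positive "
                                  "semi-definite")
        return r


def _gamma_quantile(u: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Quantile of a gamma distribution moment-matched to (mean, sd)."""
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return _gamma.ppf(u, a=shape, scale=scale)


def generate_frame(config: SimulationConfig) -> pd.DataFrame:
    """Vectorised core of the generator; returns the participants table in
    the documented CSV layout (deterministic given ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    site = rng.permutation(np.arange(n) % config.n_sites)
    arm = (rng.random(n) < config.allocation).astype(int)  # 1 = intervention

    n_paed_sites = int(round(config.paediatric_fraction * config.n_sites))
    paediatric = site < n_paed_sites
    vap = rng.random(n) < config.vap_fraction
    covid_u = rng.random(n)
    covid = np.where(covid_u < config.covid_yes_p, "yes",
                     np.where(covid_u < config.covid_yes_p + config.covid_unknown_p,
                              "unknown", "no"))
    sofa = rng.poisson(config.sofa_mean, n)
    other_inf = rng.random(n) < config.other_infection_p

    u_site_out = rng.normal(0.0, config.site_sd_logit, config.n_sites)
    u_site_cost = rng.normal(0.0, config.site_sd_logcost, config.n_sites)

    chol = np.linalg.cholesky(config.copula() + 1e-12 * np.eye(4))
    z = rng.standard_normal((n, 4)) @ chol.T
    u = _norm.cdf(z)

    p_stew = expit(logit(config.control_stewardship_p)
                   + np.log(config.intervention_stewardship_or) * arm
                   + u_site_out[site])
    p_cure = expit(logit(config.control_cure_p)
                   + np.log(config.intervention_cure_or) * arm
                   + u_site_out[site])
    p_death = expit(logit(config.mortality_28d_p) + u_site_out[site])
    stew = u[:, 0] < p_stew
    cure = u[:, 1] < p_cure
    death = u[:, 2] < p_death

    cost_mean = np.where(arm == 1, config.intervention_cost_mean,
                         config.control_cost_mean).astype(float)
    shift = np.where(vap, config.vap_intervention_cost_shift,
                     config.hap_intervention_cost_shift)
    cost_mean = cost_mean + shift * (arm == 1)
    cost_sd = np.where(arm == 1, config.intervention_cost_sd,
                       config.control_cost_sd).astype(float)
    site_mult = np.exp(u_site_cost[site] - config.site_sd_logcost**2 / 2.0)
    icu_cost = _gamma_quantile(u[:, 3], cost_mean, cost_sd) * site_mult

    gen_mean = np.where(arm == 1, config.intervention_general_cost_mean,
                        config.control_general_cost_mean).astype(float)
    gen_sd = np.where(arm == 1, config.intervention_general_cost_sd,
                      config.control_general_cost_sd).astype(float)
    general_cost = _gamma_quantile(u[:, 3], gen_mean, gen_sd) * site_mult
    total_cost = icu_cost + general_cost

    stay = np.maximum(1, np.round(icu_cost / config.per_day_icu_cost)).astype(int)
    trial_days = np.minimum(stay, TRIAL_COLLECTION_CENSOR_DAY)

    finance_missing = rng.random(n) < config.finance_missing_p
    total_missing = finance_missing | (rng.random(n) < config.total_extra_missing_p)

    rand_offset = rng.integers(0, 601, n)
    rand_dates = [_BASE_DATE + _dt.timedelta(days=int(d)) for d in rand_offset]
    discharge_dates = [rd + _dt.timedelta(days=int(s)) for rd, s in zip(rand_dates, stay)]

    panel_tests = arm * (1 + (rng.random(n) < config.panel_repeat_p).astype(int))

    df = pd.DataFrame({
        "participant_id": [f"P{i:06d}" for i in range(n)],
        "site_id": [f"S{s:02d}" for s in site],
        "arm": np.where(arm == 1, "intervention", "control"),
        "age_group": np.where(paediatric, "paediatric", "adult"),
        "infection_type": np.where(vap, "VAP", "HAP"),
        "covid_baseline": covid,
        "sofa_score": sofa.astype(float),
        "other_infection": np.where(other_inf, "yes", "no"),
        "stewardship_24h": np.where(stew, "success", "failure"),
        "cure_14d": np.where(cure, "cured", "not_cured"),
        "death_28d": np.where(death, "dead", "alive"),
        "randomisation_date": [d.isoformat() for d in rand_dates],
        "icu_discharge_date": [d.isoformat() for d in discharge_dates],
        "finance_icu_cost": np.where(finance_missing, np.nan, np.round(icu_cost, 2)),
        "finance_total_admission_cost": np.where(total_missing, np.nan,
                                                 np.round(total_cost, 2)),
        "trial_icu_days": trial_days.astype(float),
        "n_cultures": rng.poisson(config.culture_rate, n),
        "n_viral_pcr": rng.poisson(config.viral_pcr_rate, n),
        "n_xray": rng.poisson(config.xray_rate, n),
        "n_ct": rng.poisson(config.ct_rate, n),
        "panel_tests_performed": panel_tests,
    })
    return df


def _generate_courses(rng: np.random.Generator, rand_date: _dt.date) -> list[AntibioticCourse]:
    n_courses = 1 + rng.poisson(1.5)
    courses = []
    for _ in range(n_courses):
        drug, dose, route, _price = SYNTHETIC_FORMULARY[rng.integers(len(SYNTHETIC_FORMULARY))]
        start = _dt.datetime.combine(rand_date, _dt.time(hour=int(rng.integers(0, 24))))
        duration_days = int(rng.integers(3, 15))
        courses.append(AntibioticCourse(
            drug_name=drug, dose=dose,
            frequency_per_day=float(rng.integers(2, 5)),
            route=route, start=start,
            end=start + _dt.timedelta(days=duration_days),
        ))
    return courses


def generate_trial(config: SimulationConfig) -> list[ParticipantRecord]:
    """Generate one synthetic trial as a list of participant records.

    Deterministic given ``config.seed``; antibiotic courses are drawn from a
    synthetic formulary (disable with ``generate_antibiotics=False`` for
    very large runs where courses are not needed).
    """
    df = generate_frame(config)
    course_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)))
    records = []
    for row in df.itertuples(index=False):
        rand_date = _dt.date.fromisoformat(row.randomisation_date)
        courses = (
            _generate_courses(course_rng, rand_date)
            if config.generate_antibiotics else []
        )
        records.append(ParticipantRecord(
            participant_id=row.participant_id,
            site_id=row.site_id,
            arm=row.arm,
            age_group=row.age_group,
            infection_type=row.infection_type,
            covid_baseline=row.covid_baseline,
            sofa_score=row.sofa_score,
            other_infection=row.other_infection,
            stewardship_24h=row.stewardship_24h,
            cure_14d=row.cure_14d,
            death_28d=row.death_28d,
            randomisation_date=rand_date,
            icu_discharge_date=_dt.date.fromisoformat(row.icu_discharge_date),
            finance_icu_cost=None if np.isnan(row.finance_icu_cost) else float(row.finance_icu_cost),
            finance_total_admission_cost=(
                None if np.isnan(row.finance_total_admission_cost)
                else float(row.finance_total_admission_cost)
            ),
            trial_icu_days=float(row.trial_icu_days),
            resource_use=ResourceUse(
                n_cultures=int(row.n_cultures),
                n_viral_pcr=int(row.n_viral_pcr),
                n_xray=int(row.n_xray),
                n_ct=int(row.n_ct),
            ),
            antibiotic_courses=courses,
            panel_tests_performed=int(row.panel_tests_performed),
        ))
    return records


def summarize_arms(records) -> pd.DataFrame:
    """Per-arm calibration summary: N, finance ICU cost moments, outcome
    proportions, mortality, and mean panel tests.

    Cost moments are computed on finance-department costs only (the
    uncensored cost measure) so that, on generated data, they converge to
    the configured gamma moments.
    """
    rows = {}
    for arm in ("control", "intervention"):
        recs = [r for r in records if r.arm == arm]
        if not recs:
            raise ValidationError(f"no records in the {arm} arm")
        fin = np.array([r.finance_icu_cost for r in recs
                        if r.finance_icu_cost is not None], dtype=float)
        def _prop(values, positive):
            known = [v for v in values if v is not None]
            return float(np.mean([v == positive for v in known])) if known else np.nan
        rows[arm] = {
            "n": len(recs),
            "icu_cost_mean": float(fin.mean()) if len(fin) else np.nan,
            "icu_cost_sd": float(fin.std(ddof=1)) if len(fin) > 1 else np.nan,
            "stewardship_prop": _prop([r.stewardship_24h for r in recs], "success"),
            "cure_prop": _prop([r.cure_14d for r in recs], "cured"),
            "mortality_prop": _prop([r.death_28d for r in recs], "dead"),
            "mean_panel_tests": float(np.mean([r.panel_tests_performed for r in recs])),
        }
    return pd.DataFrame(rows).T.rename_axis("arm")
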