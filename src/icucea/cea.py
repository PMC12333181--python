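"""Bootstrap cost-effectiveness analysis.

Joint uncertainty in the incremental cost and incremental effect is
characterised by non-parametric bootstrap (default 1,000 resamples,
stratified by arm): each replicate refits the site-adjusted cost and
outcome models and records one (Δcost, Δeffect) pair, where Δeffect is the
marginal risk difference. From the resulting cloud the module derives

* cost-effectiveness (CE) plane quadrant shares (SE = cheaper & more
  effective, etc.),
* ICER / dominance classification of a point estimate,
* cost-effectiveness acceptability curves (CEACs): the probability that the
  incremental net monetary benefit λ·ΔE − ΔC is positive across a grid of
  willingness-to-pay values λ (by default per 1 % effect improvement),
* and a scenario suite covering the base case and the sensitivity analyses
  (finance-data-only, 14-day censoring, £200k outlier exclusion, covariate
  adjustment, total hospital costs) plus subgroup interactions.

Boundary conventions (documented, not inferred from any source): a draw
with ΔE = 0 counts as "not more effective" and ΔC = 0 as "not cost-saving"
(so the origin falls in the NW quadrant), and a net monetary benefit of
exactly zero counts as not cost-effective.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .costing import DEFAULT_PER_TEST_COST
from .estimation import (
    EffectEstimate,
    ModelFit,
    design_matrix,
    fit_binary_model,
    fit_cost_model,
    marginal_risk_difference,
    subgroup_effects,
)
from .trial_data import (
    AnalysisDataset,
    ParticipantRecord,
    build_analysis_dataset,
    censor_to_day,
    exclude_cost_outliers,
)

logger = logging.getLogger(__name__)

DEFAULT_WTP_GRID = tuple(float(x) for x in range(0, 10001, 100))
DEFAULT_OUTLIER_THRESHOLD = 200_000.0
DEFAULT_CENSOR_DAY = 14
ADJUSTMENT_COVARIATES = ("covid_baseline", "sofa_score", "other_infection")


@dataclass(frozen=True)
class CEDraw:
    """One bootstrap replicate's incremental cost / incremental effect."""

    delta_cost: float
    delta_effect: float


@dataclass
class CEACResult:
    """Probability that the intervention is cost-effective over a
    willingness-to-pay grid."""

    wtp_grid: np.ndarray
    prob_cost_effective: np.ndarray
    n_draws: int
    effect_scale: str = "per_1pct"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "wtp": self.wtp_grid,
            "prob_cost_effective": self.prob_cost_effective,
        })


@dataclass(frozen=True)
class ScenarioSpec:
    """A named analysis configuration: outcome, cost definition, dataset
    filters, covariates and bootstrap settings."""

    name: str
    outcome: str  # stewardship | cure
    cost_definition: str = "base_case"
    censor_day: Optional[int] = None
    outlier_threshold: Optional[float] = None
    covariates: tuple[str, ...] = ()
    subgroup: Optional[str] = None
    finance_only: bool = False
    n_bootstrap: int = 1000
    seed: int = 0


@dataclass
class BootstrapResult:
    """The bootstrap (Δcost, Δeffect) cloud plus per-replicate odds ratios
    and the dropped-replicate count (non-converged refits)."""

    draws: list[CEDraw]
    odds_ratios: np.ndarray
    n_dropped: int
    n_requested: int

    @property
    def delta_costs(self) -> np.ndarray:
        return np.array([d.delta_cost for d in self.draws])

    @property
    def delta_effects(self) -> np.ndarray:
        return np.array([d.delta_effect for d in self.draws])


def bootstrap_ce(dataset: AnalysisDataset, spec: ScenarioSpec) -> BootstrapResult:
    """Resample participants with replacement, stratified by arm (arm sizes
    fixed at the observed ones), refit the site-adjusted cost and outcome
    models per replicate, and collect (Δcost, Δeffect) draws.

    Replicates use site fixed effects (deterministic, robust at bootstrap
    scale); site structure is preserved through the refitted site terms.
    Replicate r draws from a generator seeded by (scenario seed, r), so any
    replicate is independently reproducible. Non-converged or separated
    replicates are dropped and counted; more than 20 % dropped raises.
    """
    t = dataset.table
    X, names = design_matrix(t, spec.covariates, site_dummies=True)
    k_arm = names.index("arm")
    y_cost = t["cost"].to_numpy(float)
    y_out = t["outcome"].to_numpy(float)
    idx_c = np.flatnonzero(t["arm_ind"].to_numpy(int) == 0)
    idx_i = np.flatnonzero(t["arm_ind"].to_numpy(int) == 1)

    draws: list[CEDraw] = []
    odds_ratios: list[float] = []
    n_dropped = 0
    for r in range(spec.n_bootstrap):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, r)))
        ii = np.concatenate([
            rng.choice(idx_c, size=len(idx_c), replace=True),
            rng.choice(idx_i, size=len(idx_i), replace=True),
        ])
        Xr = X[ii]
        keep_cols = Xr.any(axis=0)
        keep_cols[k_arm] = True
        Xk = Xr[:, keep_cols]
        k_arm_r = int(np.flatnonzero(np.flatnonzero(keep_cols) == k_arm)[0])

        beta, *_ = np.linalg.lstsq(Xk, y_cost[ii], rcond=None)
        delta_cost = float(beta[k_arm_r])

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y_out[ii], Xk).fit(disp=0, method="newton", maxiter=50)
            if not res.mle_retvals.get("converged", False) or not np.all(
                np.isfinite(res.params)
            ):
                raise np.linalg.LinAlgError("logit refit did not converge")
        except Exception:
            n_dropped += 1
            continue

        x1 = Xk.copy()
        x0 = Xk.copy()
        x1[:, k_arm_r] = 1.0
        x0[:, k_arm_r] = 0.0
        delta_effect = float(expit(x1 @ res.params).mean() - expit(x0 @ res.params).mean())
        draws.append(CEDraw(delta_cost=delta_cost, delta_effect=delta_effect))
        odds_ratios.append(float(np.exp(res.params[k_arm_r])))

    if n_dropped > 0.2 * spec.n_bootstrap:
        raise RuntimeError(
            f"{n_dropped}/{spec.n_bootstrap} bootstrap replicates dropped; "
            "the model is unstable on this dataset"
        )
    return BootstrapResult(draws, np.array(odds_ratios), n_dropped, spec.n_bootstrap)


# ---------------------------------------------------------------------------
# CE-plane geometry

def quadrant_shares(draws: Sequence[CEDraw]) -> dict[str, float]:
    """Share of draws per CE-plane quadrant.

    SE = (ΔC<0, ΔE>0), NE = (ΔC≥0, ΔE>0), SW = (ΔC<0, ΔE≤0),
    NW = (ΔC≥0, ΔE≤0). Shares sum to one exactly (NW takes the complement).
    """
    if len(draws) == 0:
        raise ValueError("quadrant shares need at least one draw")
    dc = np.array([d.delta_cost for d in draws])
    de = np.array([d.delta_effect for d in draws])
    n = len(draws)
    se = float(((dc < 0) & (de > 0)).sum() / n)
    ne = float(((dc >= 0) & (de > 0)).sum() / n)
    sw = float(((dc < 0) & (de <= 0)).sum() / n)
    nw = 1.0 - (se + ne + sw)
    return {"NE": ne, "SE": se, "SW": sw, "NW": max(nw, 0.0)}


@dataclass(frozen=True)
class DominanceResult:
    classification: str
    icer: Optional[float]
    quadrant: str


def icer_or_dominance(delta_cost: float, delta_effect: float) -> DominanceResult:
    """Classify a (Δcost, Δeffect) point: dominance when one strategy is
    both cheaper and more effective (no ratio reported), an ICER ΔC/ΔE with
    its quadrant label otherwise, and an undefined-ICER marker at ΔE = 0."""
    if not (np.isfinite(delta_cost) and np.isfinite(delta_effect)):
        raise ValueError("delta_cost and delta_effect must be finite")
    if delta_effect == 0:
        quadrant = "SW" if delta_cost < 0 else "NW"
        return DominanceResult("undefined ICER", None, quadrant)
    if delta_cost < 0 and delta_effect > 0:
        return DominanceResult("intervention dominant", None, "SE")
    if delta_cost > 0 and delta_effect < 0:
        return DominanceResult("intervention dominated", None, "NW")
    if delta_effect > 0:  # delta_cost >= 0
        return DominanceResult("more costly, more effective",
                               float(delta_cost / delta_effect), "NE")
    return DominanceResult("less costly, less effective",
                           float(delta_cost / delta_effect), "SW")


def interpretation_label(delta_cost: float, delta_effect: float) -> str:
    """Point-estimate interpretation in the vocabulary of trial-based
    economic evaluations."""
    if delta_cost < 0 and delta_effect > 0:
        return "Intervention preferred"
    if delta_cost < 0:
        return "Intervention less costly, but less effective"
    if delta_effect > 0:
        return "Intervention more costly, but more effective"
    return "Control preferred"


def ceac(
    draws: Sequence[CEDraw],
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    effect_scale: str = "per_1pct",
) -> CEACResult:
    """Cost-effectiveness acceptability curve: for each willingness-to-pay
    λ, the share of draws with positive incremental net monetary benefit
    λ·ΔE − ΔC. With ``effect_scale="per_1pct"`` the proportion-scale effect
    is multiplied by 100 so λ prices a one-percentage-point improvement."""
    grid = np.asarray(wtp_grid, float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("wtp_grid must be a strictly increasing 1-D grid")
    if effect_scale not in ("per_unit", "per_1pct"):
        raise ValueError("effect_scale must be 'per_unit' or 'per_1pct'")
    dc = np.array([d.delta_cost for d in draws])
    de = np.array([d.delta_effect for d in draws])
    if effect_scale == "per_1pct":
        de = de * 100.0
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACResult(grid, prob, n_draws=len(dc), effect_scale=effect_scale)


# ---------------------------------------------------------------------------
# Scenario suite

def default_scenarios(
    outcome: str, n_bootstrap: int = 1000, seed: int = 0
) -> list[ScenarioSpec]:
    """The base case plus the five standard sensitivity analyses for one
    outcome, each with its own reproducible seed."""
    base = dict(outcome=outcome, n_bootstrap=n_bootstrap)
    specs = [
        ScenarioSpec(name="base_case", **base),
        ScenarioSpec(name="finance_data_only", finance_only=True, **base),
        ScenarioSpec(name="censored_14_days", censor_day=DEFAULT_CENSOR_DAY, **base),
        ScenarioSpec(name="excluding_stays_over_200k",
                     outlier_threshold=DEFAULT_OUTLIER_THRESHOLD, **base),
        ScenarioSpec(name="covariate_adjusted",
                     covariates=ADJUSTMENT_COVARIATES, **base),
        ScenarioSpec(name="total_costs", cost_definition="total", **base),
    ]
    return [
        ScenarioSpec(**{**s.__dict__, "seed": seed + i}) for i, s in enumerate(specs)
    ]


@dataclass
class ScenarioResult:
    """Everything one scenario produces: adjusted estimates with bootstrap
    percentile CIs, the draw cloud, quadrant shares, CEAC, dominance
    classification and the interpretation label."""

    spec: ScenarioSpec
    n_control: int
    n_intervention: int
    cost_diff: EffectEstimate
    odds_ratio: EffectEstimate
    risk_diff: EffectEstimate
    quadrants: dict[str, float]
    ceac: CEACResult
    dominance: DominanceResult
    interpretation: str
    n_dropped_replicates: int
    draws: list[CEDraw] = field(repr=False, default_factory=list)
    exclusions: dict[str, int] = field(default_factory=dict)
    subgroups: Optional[dict] = None

    def to_row(self) -> dict:
        return {
            "scenario": self.spec.name,
            "outcome": self.spec.outcome,
            "n_control": self.n_control,
            "n_intervention": self.n_intervention,
            "cost_diff": self.cost_diff.point,
            "cost_diff_ci_low": self.cost_diff.ci_low,
            "cost_diff_ci_high": self.cost_diff.ci_high,
            "odds_ratio": self.odds_ratio.point,
            "odds_ratio_ci_low": self.odds_ratio.ci_low,
            "odds_ratio_ci_high": self.odds_ratio.ci_high,
            "risk_diff": self.risk_diff.point,
            "risk_diff_ci_low": self.risk_diff.ci_low,
            "risk_diff_ci_high": self.risk_diff.ci_high,
            "se_share": self.quadrants["SE"],
            "sw_share": self.quadrants["SW"],
            "ne_share": self.quadrants["NE"],
            "nw_share": self.quadrants["NW"],
            "icer": self.dominance.icer,
            "classification": self.dominance.classification,
            "interpretation": self.interpretation,
            "n_dropped_replicates": self.n_dropped_replicates,
        }


def prepare_dataset(
    records: Sequence[ParticipantRecord],
    spec: ScenarioSpec,
    *,
    per_day_icu_cost: float,
    per_test: float = DEFAULT_PER_TEST_COST,
) -> AnalysisDataset:
    """Apply a scenario's dataset pipeline: analysis-set construction, then
    optional day-censoring and outlier exclusion."""
    ds = build_analysis_dataset(
        records, spec.outcome, spec.cost_definition,
        per_day_icu_cost=per_day_icu_cost, per_test=per_test,
        finance_only=spec.finance_only,
    )
    if spec.censor_day is not None:
        ds = censor_to_day(ds, spec.censor_day)
    if spec.outlier_threshold is not None:
        ds = exclude_cost_outliers(ds, spec.outlier_threshold)
    return ds


def _percentile_ci(values: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def run_scenario(
    records: Sequence[ParticipantRecord],
    spec: ScenarioSpec,
    *,
    per_day_icu_cost: float,
    per_test: float = DEFAULT_PER_TEST_COST,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    effect_scale: str = "per_1pct",
    point_method: str = "auto",
) -> ScenarioResult:
    """Run one scenario end to end: dataset pipeline, site-adjusted point
    estimates, bootstrap CIs, CE plane and CEAC."""
    ds = prepare_dataset(records, spec, per_day_icu_cost=per_day_icu_cost,
                         per_test=per_test)
    cost_fit = fit_cost_model(ds, spec.covariates, method=point_method)
    bin_fit = fit_binary_model(ds, spec.covariates, method=point_method)
    risk = marginal_risk_difference(bin_fit, ds)

    boot = bootstrap_ce(ds, spec)
    cost_est = cost_fit.estimate
    cost_est.ci_low, cost_est.ci_high = _percentile_ci(boot.delta_costs)
    or_est = bin_fit.estimate
    or_est.ci_low, or_est.ci_high = _percentile_ci(boot.odds_ratios)
    risk.ci_low, risk.ci_high = _percentile_ci(boot.delta_effects)

    quadrants = quadrant_shares(boot.draws)
    curve = ceac(boot.draws, wtp_grid, effect_scale)
    dom = icer_or_dominance(cost_est.point, risk.point)
    label = interpretation_label(cost_est.point, risk.point)

    subgroups = None
    if spec.subgroup is not None:
        subgroups = subgroup_effects(ds, spec.subgroup)

    return ScenarioResult(
        spec=spec, n_control=ds.n_control, n_intervention=ds.n_intervention,
        cost_diff=cost_est, odds_ratio=or_est, risk_diff=risk,
        quadrants=quadrants, ceac=curve, dominance=dom, interpretation=label,
        n_dropped_replicates=boot.n_dropped, draws=boot.draws,
        exclusions=ds.exclusions, subgroups=subgroups,
    )


def run_scenario_suite(
    records: Sequence[ParticipantRecord],
    specs: Sequence[ScenarioSpec],
    *,
    per_day_icu_cost: float,
    per_test: float = DEFAULT_PER_TEST_COST,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    effect_scale: str = "per_1pct",
    point_method: str = "auto",
) -> tuple[list[ScenarioResult], dict[str, str]]:
    """Run every scenario, isolating failures: a scenario that errors is
    recorded in the returned failure map and the others proceed."""
    results: list[ScenarioResult] = []
    failures: dict[str, str] = {}
    for spec in specs:
        try:
            results.append(run_scenario(
                records, spec, per_day_icu_cost=per_day_icu_cost,
                per_test=per_test, wtp_grid=wtp_grid,
                effect_scale=effect_scale, point_method=point_method,
            ))
        except Exception as exc:  # isolate per-scenario failures
            logger.error("scenario %s failed: %s", spec.name, exc)
            failures[spec.name] = str(exc)
    return results, failures


def suite_summary_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Scenario-by-scenario summary table (one row per scenario)."""
    return pd.DataFrame([r.to_row() for r in results])


def draws_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Long-format CE-plane draws across scenarios."""
    rows = []
    for r in results:
        for k, d in enumerate(r.draws):
            rows.append({
                "scenario": r.spec.name, "outcome": r.spec.outcome,
                "replicate": k, "delta_cost": d.delta_cost,
                "delta_effect": d.delta_effect,
            })
    return pd.DataFrame(rows)


def ceac_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Long-format CEACs across scenarios."""
    rows = []
    for r in results:
        for wtp, p in zip(r.ceac.wtp_grid, r.ceac.prob_cost_effective):
            rows.append({
                "scenario": r.spec.name, "outcome": r.spec.outcome,
                "wtp": wtp, "prob_cost_effective": p,
            })
    return pd.DataFrame(rows)
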