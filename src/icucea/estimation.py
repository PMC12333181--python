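"""Site-adjusted treatment-effect estimation.

The trial randomised individuals within 14 ICUs, so treatment effects are
estimated adjusting for site at minimum: linear mixed models (site random
intercept) for costs, logistic mixed models for the binary co-primary
outcomes, with odds ratios converted to marginal risk differences by
standardization — the risk-difference scale is what the cost-effectiveness
plane uses.

Backends
--------
* Costs: :class:`statsmodels.regression.mixed_linear_model.MixedLM`. When
  the site variance component is degenerate (zero or non-converged), the
  model deterministically falls back to OLS with site fixed effects and the
  result is flagged; with 14 sites the two are near-identical and the
  fallback keeps bootstrap replicates well-defined.
* Binary outcomes: variational-Bayes logistic mixed model
  (:class:`statsmodels.genmod.bayes_mixed_glm.BinomialBayesMixedGLM`), with
  the analogous fallback to a logit with site fixed effects. A single-site
  dataset is fitted as a plain logit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from .trial_data import AnalysisDataset

logger = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))


class EstimationError(RuntimeError):
    """A model cannot be fitted on the given dataset."""


class SeparationError(EstimationError):
    """The outcome is (quasi-)separated, e.g. constant within an arm."""


@dataclass
class EffectEstimate:
    """A treatment-effect estimate (intervention vs control) with its scale,
    interval and provenance."""

    quantity: str  # cost_diff | odds_ratio | risk_diff
    point: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    se: Optional[float] = None
    n_control: int = 0
    n_intervention: int = 0
    method: str = "unadjusted"
    converged: bool = True

    def __post_init__(self) -> None:
        if self.quantity == "odds_ratio" and self.point <= 0:
            raise ValueError("odds ratio must be positive")

    def to_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "se": self.se,
            "n_control": self.n_control,
            "n_intervention": self.n_intervention,
            "method": self.method,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Unadjusted comparison

def unadjusted_mean_difference(
    control: Sequence[float], intervention: Sequence[float]
) -> EffectEstimate:
    """Intervention-minus-control difference in mean cost with a Welch
    normal-approximation 95% CI (Welch–Satterthwaite degrees of freedom)."""
    c = np.asarray(control, float)
    i = np.asarray(intervention, float)
    if len(c) < 2 or len(i) < 2:
        raise EstimationError("each arm needs at least 2 observations")
    diff = i.mean() - c.mean()
    vc, vi = c.var(ddof=1) / len(c), i.var(ddof=1) / len(i)
    se = float(np.sqrt(vc + vi))
    if se > 0:
        df = (vc + vi) ** 2 / (vc**2 / (len(c) - 1) + vi**2 / (len(i) - 1))
        tq = float(stats.t.ppf(0.975, df))
    else:
        tq = Z975
    return EffectEstimate(
        quantity="cost_diff", point=float(diff),
        ci_low=float(diff - tq * se), ci_high=float(diff + tq * se), se=se,
        n_control=len(c), n_intervention=len(i), method="unadjusted",
    )


# ---------------------------------------------------------------------------
# Design matrices

_COVARIATES = ("covid_baseline", "sofa_score", "other_infection")


def design_matrix(
    table: pd.DataFrame,
    covariates: Sequence[str] = (),
    site_dummies: bool = True,
    arm_value: Optional[int] = None,
) -> tuple[np.ndarray, list[str]]:
    """Build the fixed-effects design: intercept, arm indicator, optional
    baseline covariates, optional site fixed effects (first site as
    reference). ``arm_value`` overrides the arm column (for marginal
    standardization)."""
    n = len(table)
    cols: dict[str, np.ndarray] = {"const": np.ones(n)}
    if arm_value is None:
        cols["arm"] = table["arm_ind"].to_numpy(float)
    else:
        cols["arm"] = np.full(n, float(arm_value))
    for cov in covariates:
        if cov == "sofa_score":
            v = table["sofa_score"].to_numpy(float)
            med = np.nanmedian(v)
            cols["sofa_score"] = np.where(np.isnan(v), med, v)
        elif cov == "covid_baseline":
            raw = table["covid_baseline"].to_numpy(str)
            cols["covid_yes"] = (raw == "yes").astype(float)
            cols["covid_unknown"] = (raw == "unknown").astype(float)
        elif cov == "other_infection":
            cols["other_infection"] = (
                table["other_infection"].to_numpy(str) == "yes"
            ).astype(float)
        else:
            raise ValueError(f"unknown covariate {cov!r}; supported: {_COVARIATES}")
    if site_dummies:
        sites = sorted(table["site_id"].unique())
        for s in sites[1:]:
            cols[f"site_{s}"] = (table["site_id"] == s).to_numpy(float)
    names = list(cols)
    return np.column_stack([cols[k] for k in names]), names


@dataclass
class ModelFit:
    """A fitted arm-effect model: the headline estimate plus the fixed-effect
    coefficients needed for prediction/standardization."""

    estimate: EffectEstimate
    params: np.ndarray = field(repr=False)
    columns: list[str] = field(default_factory=list)
    covariates: tuple[str, ...] = ()
    site_dummies: bool = False
    method: str = ""


# ---------------------------------------------------------------------------
# Cost model

def fit_cost_model(
    dataset: AnalysisDataset,
    covariates: Sequence[str] = (),
    method: str = "auto",
) -> ModelFit:
    """Linear model of analysis cost on arm (+ covariates), adjusted for
    site. ``method``: "auto" (random intercept with fixed-effects fallback)
    or "fixed" (site fixed effects directly). The arm coefficient is the
    adjusted cost difference."""
    t = dataset.table
    if t["site_id"].nunique() < 2:
        raise EstimationError(
            "only one site present: site adjustment is not identified; "
            "use unadjusted_mean_difference"
        )
    y = t["cost"].to_numpy(float)
    n_c, n_i = dataset.n_control, dataset.n_intervention

    if method == "auto":
        X, names = design_matrix(t, covariates, site_dummies=False)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                res = sm.MixedLM(y, X, groups=t["site_id"].to_numpy()).fit(reml=True)
            re_var = float(np.asarray(res.cov_re)[0, 0])
            degenerate = (not res.converged) or re_var < 1e-8 * max(y.var(), 1.0)
        except (np.linalg.LinAlgError, ValueError):
            degenerate = True
            res = None
        if res is not None and not degenerate:
            k = names.index("arm")
            point, se = float(res.fe_params[k]), float(res.bse_fe[k])
            est = EffectEstimate(
                quantity="cost_diff", point=point,
                ci_low=point - Z975 * se, ci_high=point + Z975 * se, se=se,
                n_control=n_c, n_intervention=n_i, method="site_random",
            )
            return ModelFit(est, np.asarray(res.fe_params), names,
                            tuple(covariates), False, "site_random")
        logger.warning(
            "site variance component degenerate or non-converged; "
            "falling back to site fixed effects"
        )

    X, names = design_matrix(t, covariates, site_dummies=True)
    res = sm.OLS(y, X).fit()
    k = names.index("arm")
    point, se = float(res.params[k]), float(res.bse[k])
    est = EffectEstimate(
        quantity="cost_diff", point=point,
        ci_low=point - Z975 * se, ci_high=point + Z975 * se, se=se,
        n_control=n_c, n_intervention=n_i, method="site_fixed",
        converged=method == "fixed",
    )
    return ModelFit(est, np.asarray(res.params), names,
                    tuple(covariates), True, "site_fixed")


# ---------------------------------------------------------------------------
# Binary-outcome model

def _check_separation(t: pd.DataFrame) -> None:
    for arm in ("control", "intervention"):
        y = t.loc[t["arm"] == arm, "outcome"]
        if y.nunique() < 2:
            raise SeparationError(
                f"outcome {y.iloc[0]!r} is constant in the {arm} arm; the "
                "odds ratio is not identified"
            )


def fit_binary_model(
    dataset: AnalysisDataset,
    covariates: Sequence[str] = (),
    method: str = "auto",
) -> ModelFit:
    """Logistic model of the outcome on arm (+ covariates) with site random
    intercept (variational Bayes), falling back to — or forced onto, with
    ``method="fixed"`` — a logit with site fixed effects. The exponentiated
    arm coefficient is the adjusted odds ratio."""
    t = dataset.table
    _check_separation(t)
    y = t["outcome"].to_numpy(float)
    n_c, n_i = dataset.n_control, dataset.n_intervention
    multi_site = t["site_id"].nunique() >= 2

    if method == "auto" and multi_site:
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        X, names = design_matrix(t, covariates, site_dummies=False)
        sites = sorted(t["site_id"].unique())
        exog_vc = np.column_stack(
            [(t["site_id"] == s).to_numpy(float) for s in sites]
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = BinomialBayesMixedGLM(
                    y, X, exog_vc, ident=np.zeros(len(sites), dtype=int)
                ).fit_vb()
            k = names.index("arm")
            coef, se = float(res.fe_mean[k]), float(res.fe_sd[k])
            if np.isfinite(coef) and np.isfinite(se) and se > 0:
                est = EffectEstimate(
                    quantity="odds_ratio", point=float(np.exp(coef)),
                    ci_low=float(np.exp(coef - Z975 * se)),
                    ci_high=float(np.exp(coef + Z975 * se)),
                    se=se, n_control=n_c, n_intervention=n_i,
                    method="site_random_vb",
                )
                return ModelFit(est, np.asarray(res.fe_mean), names,
                                tuple(covariates), False, "site_random_vb")
        except (np.linalg.LinAlgError, ValueError):
            pass
        logger.warning("logistic mixed model failed; falling back to site "
                       "fixed effects")

    X, names = design_matrix(t, covariates, site_dummies=multi_site)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
        if not res.mle_retvals.get("converged", False):
            raise EstimationError("logit did not converge")
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logit fit failed: {exc}") from exc
    k = names.index("arm")
    coef, se = float(res.params[k]), float(res.bse[k])
    fit_method = "site_fixed" if multi_site else "single_site"
    est = EffectEstimate(
        quantity="odds_ratio", point=float(np.exp(coef)),
        ci_low=float(np.exp(coef - Z975 * se)),
        ci_high=float(np.exp(coef + Z975 * se)),
        se=se, n_control=n_c, n_intervention=n_i, method=fit_method,
    )
    return ModelFit(est, np.asarray(res.params), names,
                    tuple(covariates), multi_site, fit_method)


def marginal_risk_difference(fit: ModelFit, dataset: AnalysisDataset) -> EffectEstimate:
    """Average marginal effect of the intervention by marginal
    standardization: mean predicted probability with every participant set
    to intervention minus the mean with every participant set to control,
    site random intercepts at zero (fixed-effect site terms kept at their
    observed values). On a saturated single-site model this reproduces the
    raw proportion difference exactly."""
    t = dataset.table
    x1, _ = design_matrix(t, fit.covariates, site_dummies=fit.site_dummies, arm_value=1)
    x0, _ = design_matrix(t, fit.covariates, site_dummies=fit.site_dummies, arm_value=0)
    p1 = expit(x1 @ fit.params)
    p0 = expit(x0 @ fit.params)
    return EffectEstimate(
        quantity="risk_diff", point=float(p1.mean() - p0.mean()),
        n_control=dataset.n_control, n_intervention=dataset.n_intervention,
        method=fit.method,
    )


# ---------------------------------------------------------------------------
# Subgroup interactions

SUBGROUPS = ("age_group", "covid_baseline", "infection_type")


def subgroup_effects(
    dataset: AnalysisDataset, subgroup: str
) -> dict[str, dict[str, EffectEstimate]]:
    """Per-level treatment effects from arm-by-subgroup interaction models
    (site fixed effects): for each subgroup level, the cost difference and
    the outcome odds ratio with Wald CIs. Levels with an empty arm cell are
    skipped with a warning; a single-level subgroup degenerates to the main
    effect."""
    if subgroup not in SUBGROUPS:
        raise ValueError(f"subgroup must be one of {SUBGROUPS}")
    t = dataset.table
    levels = sorted(t[subgroup].unique())
    usable = []
    for lv in levels:
        sub = t[t[subgroup] == lv]
        if sub["arm"].nunique() < 2:
            logger.warning("subgroup %s=%s lacks one arm; skipped", subgroup, lv)
            continue
        usable.append(lv)
    if len(usable) == 1:
        cost = fit_cost_model(dataset, method="fixed").estimate
        orr = fit_binary_model(dataset, method="fixed").estimate
        return {usable[0]: {"cost_diff": cost, "odds_ratio": orr}}

    t = t[t[subgroup].isin(usable)].reset_index(drop=True)
    ref, others = usable[0], usable[1:]
    X_base, names = design_matrix(t, (), site_dummies=True)
    extra, extra_names = [], []
    for lv in others:
        ind = (t[subgroup] == lv).to_numpy(float)
        extra += [ind, ind * t["arm_ind"].to_numpy(float)]
        extra_names += [f"{subgroup}_{lv}", f"arm_x_{lv}"]
    X = np.column_stack([X_base] + extra)
    names = names + extra_names
    k_arm = names.index("arm")

    def _level_effect(params, cov, lv) -> tuple[float, float]:
        if lv == ref:
            return float(params[k_arm]), float(np.sqrt(cov[k_arm, k_arm]))
        k_int = names.index(f"arm_x_{lv}")
        point = params[k_arm] + params[k_int]
        var = cov[k_arm, k_arm] + cov[k_int, k_int] + 2 * cov[k_arm, k_int]
        return float(point), float(np.sqrt(max(var, 0.0)))

    out: dict[str, dict[str, EffectEstimate]] = {}
    y_cost = t["cost"].to_numpy(float)
    ols = sm.OLS(y_cost, X).fit()
    _check_separation(t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        logit = sm.Logit(t["outcome"].to_numpy(float), X).fit(disp=0, maxiter=100)
    for lv in usable:
        sub = t[t[subgroup] == lv]
        n_c = int((sub["arm"] == "control").sum())
        n_i = int((sub["arm"] == "intervention").sum())
        cpt, cse = _level_effect(ols.params, np.asarray(ols.cov_params()), lv)
        lpt, lse = _level_effect(logit.params, np.asarray(logit.cov_params()), lv)
        out[lv] = {
            "cost_diff": EffectEstimate(
                "cost_diff", cpt, cpt - Z975 * cse, cpt + Z975 * cse, cse,
                n_c, n_i, "site_fixed_interaction"),
            "odds_ratio": EffectEstimate(
                "odds_ratio", float(np.exp(lpt)),
                float(np.exp(lpt - Z975 * lse)), float(np.exp(lpt + Z975 * lse)),
                lse, n_c, n_i, "site_fixed_interaction"),
        }
    return out
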