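"""Published summary statistics of the multicentre HAP/VAP trial that the
synthetic generator emulates.

Individual patient data from the trial are not publicly released, so the
package carries the *published arm-level summaries* (unadjusted cost means
and SDs, outcome counts) as calibration inputs: the simulator's defaults are
derived from them, and the unadjusted-arithmetic checks recompute arm
differences and proportions directly from them.

Cost summaries are GBP at 2020/21 prices; entries are (mean, sd, n).
Outcome entries are (events, n).
"""

from __future__ import annotations

#: Unadjusted per-arm cost summaries: component -> arm -> (mean, sd, n).
ARM_COST_SUMMARY: dict[str, dict[str, tuple[float, float, int]]] = {
    # Pneumonia panel per-person cost (repeat tests push the mean above the
    # £196 per-test estimate).
    "panel": {"control": (0.0, 0.0, 261), "intervention": (198.0, 17.0, 268)},
    # ICU stay from randomisation (finance income, trial-collected fallback).
    "icu": {"control": (40951.0, 53658.0, 261), "intervention": (32951.0, 36989.0, 268)},
    # Base case = panel + ICU stay from randomisation.
    "base_case": {"control": (40951.0, 53658.0, 261), "intervention": (33149.0, 36989.0, 268)},
    # Total = panel + all ICU stay(s) + general admission income
    # (whole-admission finance data available for a subset only).
    "total": {"control": (75998.0, 82935.0, 212), "intervention": (64459.0, 59709.0, 216)},
}

#: Binary outcome counts: outcome -> arm -> (events, n).
OUTCOME_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "stewardship": {"control": (147, 263), "intervention": (205, 268)},
    "cure": {"control": (171, 265), "intervention": (152, 268)},
}

#: Pooled 28-day mortality among participants with finance costs and cure
#: data: (deaths, n).
MORTALITY_28D_POOLED: tuple[int, int] = (137, 461)

#: Participants with resolved ICU costs and at least one outcome, and the
#: subset whose cost came from trial-collected days rather than finance data.
N_COSTED = 529
N_TRIAL_COLLECTED_ONLY = 61

#: Adjusted odds ratios for the arm effect (site-adjusted analyses) used as
#: the generator's effect-size defaults.
STEWARDSHIP_ODDS_RATIO = 2.51
CURE_ODDS_RATIO = 0.689


def unadjusted_cost_differences() -> dict[str, float]:
    """Intervention-minus-control differences in mean cost per component."""
    return {
        component: arms["intervention"][0] - arms["control"][0]
        for component, arms in ARM_COST_SUMMARY.items()
    }


def outcome_proportions_pct() -> dict[str, dict[str, float]]:
    """Arm-level outcome proportions in percent, from the published counts."""
    return {
        outcome: {
            arm: 100.0 * events / n
            for arm, (events, n) in arms.items()
        }
        for outcome, arms in OUTCOME_COUNTS.items()
    }


def pooled_mortality_pct() -> float:
    deaths, n = MORTALITY_28D_POOLED
    return 100.0 * deaths / n
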