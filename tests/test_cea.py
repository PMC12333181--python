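"""Bootstrap CE clouds, quadrant geometry, ICER/dominance, CEACs and the
scenario suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import PER_DAY, PER_TEST
from icucea.cea import (
    CEDraw,
    ScenarioSpec,
    bootstrap_ce,
    ceac,
    default_scenarios,
    icer_or_dominance,
    interpretation_label,
    quadrant_shares,
    run_scenario,
    run_scenario_suite,
    suite_summary_frame,
)
from icucea.estimation import fit_cost_model
from icucea.trial_data import AnalysisDataset

EXAMPLE_DRAWS = [CEDraw(-5, 0.1), CEDraw(3, 0.2), CEDraw(2, -0.1)]


def _arm_constant_dataset(n_per_arm=40, cost_gap=100.0) -> AnalysisDataset:
    """Costs constant within arm (intervention = control - gap); outcome
    varies so the logistic refit is well-posed."""
    rng = np.random.default_rng(5)
    rows = []
    for arm, ind, cost in [("control", 0, 10_000.0),
                           ("intervention", 1, 10_000.0 - cost_gap)]:
        for k in range(n_per_arm):
            rows.append({
                "participant_id": f"{arm}{k}", "site_id": f"S{k % 2}",
                "arm": arm, "arm_ind": ind, "age_group": "adult",
                "infection_type": "VAP", "covid_baseline": "no",
                "sofa_score": 5.0, "other_infection": "no",
                "outcome": int(rng.random() < 0.6), "icu_cost": cost,
                "stay_days": 5.0, "cost_source": "finance",
                "panel_cost": 0.0, "cost": cost,
            })
    return AnalysisDataset(pd.DataFrame(rows), "stewardship", "base_case", PER_DAY)


class TestBootstrap:
    def test_deterministic_given_seed(self, ds530_stewardship):
        spec = ScenarioSpec(name="b", outcome="stewardship", n_bootstrap=50, seed=4)
        a = bootstrap_ce(ds530_stewardship, spec)
        b = bootstrap_ce(ds530_stewardship, spec)
        assert a.draws == b.draws
        other = bootstrap_ce(ds530_stewardship,
                             ScenarioSpec(name="b", outcome="stewardship",
                                          n_bootstrap=50, seed=5))
        assert a.draws != other.draws

    def test_arm_constant_costs_give_degenerate_cost_draws(self):
        ds = _arm_constant_dataset(cost_gap=100.0)
        spec = ScenarioSpec(name="d", outcome="stewardship", n_bootstrap=50, seed=0)
        boot = bootstrap_ce(ds, spec)
        assert np.allclose(boot.delta_costs, -100.0, atol=1e-8)

    def test_draw_means_near_generating_truth(self, ds5000_stewardship):
        spec = ScenarioSpec(name="t", outcome="stewardship", n_bootstrap=100, seed=2)
        boot = bootstrap_ce(ds5000_stewardship, spec)
        truth_cost = (32_951.0 + 196.0 * 1.0102) - 40_951.0
        assert abs(boot.delta_costs.mean() - truth_cost) < 4_000
        assert boot.delta_effects.mean() == pytest.approx(0.202, abs=0.04)
        assert boot.n_dropped == 0

    def test_percentile_interval_covers_point_estimate(self, ds530_stewardship):
        covered = 0
        point = fit_cost_model(ds530_stewardship, method="fixed").estimate.point
        for seed in range(10):
            spec = ScenarioSpec(name="c", outcome="stewardship",
                                n_bootstrap=100, seed=1000 + seed)
            boot = bootstrap_ce(ds530_stewardship, spec)
            lo, hi = np.percentile(boot.delta_costs, [2.5, 97.5])
            covered += lo <= point <= hi
        assert covered >= 9

    def test_excessive_dropped_replicates_raise(self):
        # 6-per-arm dataset with near-constant outcome: resampling often
        # yields a constant arm and the logistic refit fails
        rng = np.random.default_rng(0)
        rows = []
        for arm, ind in [("control", 0), ("intervention", 1)]:
            for k in range(6):
                rows.append({
                    "participant_id": f"{arm}{k}", "site_id": "S0", "arm": arm,
                    "arm_ind": ind, "age_group": "adult",
                    "infection_type": "VAP", "covid_baseline": "no",
                    "sofa_score": 5.0, "other_infection": "no",
                    "outcome": 1 if (arm == "intervention" or k > 0) else 0,
                    "icu_cost": float(rng.integers(5, 50) * 1000),
                    "stay_days": 5.0, "cost_source": "finance",
                    "panel_cost": 0.0, "cost": 10_000.0,
                })
        ds = AnalysisDataset(pd.DataFrame(rows), "stewardship", "base_case", PER_DAY)
        spec = ScenarioSpec(name="sep", outcome="stewardship",
                            n_bootstrap=100, seed=0)
        with pytest.raises(RuntimeError, match="dropped"):
            bootstrap_ce(ds, spec)


class TestQuadrantShares:
    def test_enumerated_example(self):
        shares = quadrant_shares(EXAMPLE_DRAWS)
        assert shares == {"NE": pytest.approx(1 / 3), "SE": pytest.approx(1 / 3),
                          "SW": 0.0, "NW": pytest.approx(1 / 3)}

    def test_all_south_east(self):
        shares = quadrant_shares([CEDraw(-1, 0.01)] * 5)
        assert shares["SE"] == 1.0

    def test_origin_counts_north_west(self):
        assert quadrant_shares([CEDraw(0.0, 0.0)])["NW"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quadrant_shares([])

    @given(st.lists(st.tuples(st.floats(-1e5, 1e5), st.floats(-1, 1)),
                    min_size=1, max_size=200))
    def test_shares_sum_to_one_exactly(self, points):
        draws = [CEDraw(dc, de) for dc, de in points]
        shares = quadrant_shares(draws)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(0 <= v <= 1 for v in shares.values())


class TestIcerOrDominance:
    @pytest.mark.parametrize("dc,de,classification,icer,quadrant", [
        (100.0, 0.05, "more costly, more effective", 2000.0, "NE"),
        (-7_373.0, 0.20, "intervention dominant", None, "SE"),
        (-7_147.0, -0.08, "less costly, less effective", 89_337.5, "SW"),
        (5_000.0, -0.1, "intervention dominated", None, "NW"),
        (-5.0, 0.0, "undefined ICER", None, "SW"),
        (0.0, 0.0, "undefined ICER", None, "NW"),
    ])
    def test_classification(self, dc, de, classification, icer, quadrant):
        res = icer_or_dominance(dc, de)
        assert res.classification == classification
        assert res.quadrant == quadrant
        if icer is None:
            assert res.icer is None
        else:
            assert res.icer == pytest.approx(icer)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            icer_or_dominance(np.nan, 0.1)

    def test_interpretation_labels(self):
        assert interpretation_label(-1, 0.1) == "Intervention preferred"
        assert interpretation_label(-1, -0.1) == (
            "Intervention less costly, but less effective")
        assert interpretation_label(1, 0.1) == (
            "Intervention more costly, but more effective")
        assert interpretation_label(1, -0.1) == "Control preferred"


class TestCEAC:
    def test_enumerated_example_per_unit(self):
        res = ceac(EXAMPLE_DRAWS, wtp_grid=[20.0], effect_scale="per_unit")
        # NMBs: 20*0.1+5=7, 20*0.2-3=1, 20*(-0.1)-2=-4
        assert res.prob_cost_effective[0] == pytest.approx(2 / 3)

    def test_zero_wtp_is_probability_of_saving_money(self):
        res = ceac(EXAMPLE_DRAWS, wtp_grid=[1e-9, 1.0])
        share_cheaper = np.mean([d.delta_cost < 0 for d in EXAMPLE_DRAWS])
        res0 = ceac(EXAMPLE_DRAWS, wtp_grid=[0.0, 1.0])
        assert res0.prob_cost_effective[0] == pytest.approx(share_cheaper)
        assert res.prob_cost_effective[0] == pytest.approx(share_cheaper)

    def test_large_wtp_approaches_probability_of_effect_gain(self):
        res = ceac(EXAMPLE_DRAWS, wtp_grid=[1e12])
        share_effective = np.mean([d.delta_effect > 0 for d in EXAMPLE_DRAWS])
        assert res.prob_cost_effective[0] == pytest.approx(share_effective)

    def test_per_1pct_scale_equals_rescaled_per_unit(self):
        grid = [10.0, 50.0, 200.0]
        per_pct = ceac(EXAMPLE_DRAWS, wtp_grid=grid, effect_scale="per_1pct")
        per_unit = ceac(EXAMPLE_DRAWS, wtp_grid=[100 * g for g in grid],
                        effect_scale="per_unit")
        assert np.allclose(per_pct.prob_cost_effective,
                           per_unit.prob_cost_effective)

    def test_consistent_with_quadrant_shares(self, ds530_stewardship):
        spec = ScenarioSpec(name="q", outcome="stewardship", n_bootstrap=100, seed=9)
        boot = bootstrap_ce(ds530_stewardship, spec)
        shares = quadrant_shares(boot.draws)
        res = ceac(boot.draws, wtp_grid=[0.0, 1e9])
        assert res.prob_cost_effective[0] == pytest.approx(
            shares["SE"] + shares["SW"])
        assert res.prob_cost_effective[-1] == pytest.approx(
            shares["SE"] + shares["NE"])

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            ceac(EXAMPLE_DRAWS, wtp_grid=[10.0, 10.0])


class TestScenarioSuite:
    @pytest.fixture(scope="class")
    def stewardship_results(self, trial530):
        specs = default_scenarios("stewardship", n_bootstrap=100, seed=11)
        results, failures = run_scenario_suite(
            trial530, specs, per_day_icu_cost=PER_DAY, per_test=PER_TEST)
        assert failures == {}
        return results

    def test_all_scenarios_produce_rows(self, stewardship_results):
        frame = suite_summary_frame(stewardship_results)
        assert list(frame["scenario"]) == [
            "base_case", "finance_data_only", "censored_14_days",
            "excluding_stays_over_200k", "covariate_adjusted", "total_costs"]
        assert (frame["n_control"] >= 1).all()

    def test_stewardship_scenarios_prefer_intervention(self, stewardship_results):
        # generating truth: cheaper and more effective for every scenario
        # except 14-day censoring, whose generating cost difference is
        # slightly positive under the calibrated gamma stays
        frame = suite_summary_frame(stewardship_results).set_index("scenario")
        for scen in ["base_case", "finance_data_only",
                     "excluding_stays_over_200k", "covariate_adjusted",
                     "total_costs"]:
            assert frame.loc[scen, "cost_diff"] < 0
            assert frame.loc[scen, "risk_diff"] > 0
            assert frame.loc[scen, "interpretation"] == "Intervention preferred"
        assert frame.loc["censored_14_days", "risk_diff"] > 0

    def test_cure_scenario_less_costly_less_effective(self, trial530):
        spec = ScenarioSpec(name="base_case", outcome="cure",
                            n_bootstrap=100, seed=17)
        res = run_scenario(trial530, spec, per_day_icu_cost=PER_DAY,
                           per_test=PER_TEST)
        assert res.cost_diff.point < 0
        assert res.risk_diff.point < 0
        assert res.interpretation == (
            "Intervention less costly, but less effective")
        assert res.quadrants["SW"] > 0.5

    def test_bootstrap_cis_bracket_points(self, stewardship_results):
        for r in stewardship_results:
            assert r.cost_diff.ci_low <= r.cost_diff.point <= r.cost_diff.ci_high
            assert r.risk_diff.ci_low <= r.risk_diff.point <= r.risk_diff.ci_high

    def test_empty_spec_list_yields_empty_results(self, trial530):
        results, failures = run_scenario_suite(
            trial530, [], per_day_icu_cost=PER_DAY, per_test=PER_TEST)
        assert results == [] and failures == {}

    def test_failures_are_isolated(self, trial530):
        bad = ScenarioSpec(name="broken", outcome="stewardship",
                           covariates=("not_a_covariate",), n_bootstrap=20, seed=1)
        good = ScenarioSpec(name="base_case", outcome="stewardship",
                            n_bootstrap=20, seed=2)
        results, failures = run_scenario_suite(
            trial530, [bad, good], per_day_icu_cost=PER_DAY, per_test=PER_TEST)
        assert [r.spec.name for r in results] == ["base_case"]
        assert "broken" in failures

    def test_subgroup_scenario_reports_levels(self, trial530):
        spec = ScenarioSpec(name="by_infection", outcome="stewardship",
                            subgroup="infection_type", n_bootstrap=20, seed=3)
        res = run_scenario(trial530, spec, per_day_icu_cost=PER_DAY,
                           per_test=PER_TEST)
        assert set(res.subgroups) == {"HAP", "VAP"}
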