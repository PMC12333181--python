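import datetime as dt

import pytest
from hypothesis import settings

from icucea.synthetic_trial import SimulationConfig, generate_trial
from icucea.trial_data import ParticipantRecord, build_analysis_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

PER_DAY = 2000.0
PER_TEST = 196.0


def make_record(
    pid: str,
    arm: str = "control",
    site: str = "S00",
    finance_icu_cost=None,
    trial_icu_days=None,
    stay_days=None,
    stewardship="success",
    cure="cured",
    finance_total=None,
    panel_tests=None,
    **kwargs,
) -> ParticipantRecord:
    """Build a small hand-specified participant; ``stay_days`` sets the
    randomisation/discharge dates accordingly."""
    rand = dt.date(2020, 1, 1)
    discharge = rand + dt.timedelta(days=int(stay_days)) if stay_days else None
    if panel_tests is None:
        panel_tests = 1 if arm == "intervention" else 0
    return ParticipantRecord(
        participant_id=pid,
        site_id=site,
        arm=arm,
        stewardship_24h=stewardship,
        cure_14d=cure,
        death_28d="alive",
        randomisation_date=rand,
        icu_discharge_date=discharge,
        finance_icu_cost=finance_icu_cost,
        finance_total_admission_cost=finance_total,
        trial_icu_days=trial_icu_days,
        panel_tests_performed=panel_tests,
        **kwargs,
    )


@pytest.fixture(scope="session")
def trial530():
    """Default-condition synthetic trial at the published scale."""
    return generate_trial(SimulationConfig(n_participants=530, seed=7))


@pytest.fixture(scope="session")
def ds530_stewardship(trial530):
    return build_analysis_dataset(
        trial530, "stewardship", per_day_icu_cost=PER_DAY, per_test=PER_TEST
    )


@pytest.fixture(scope="session")
def trial5000():
    """Larger trial (no site effects) for parameter-recovery checks."""
    cfg = SimulationConfig(
        n_participants=5000, seed=5, site_sd_logit=0.0, site_sd_logcost=0.0,
        generate_antibiotics=False,
    )
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def ds5000_stewardship(trial5000):
    return build_analysis_dataset(
        trial5000, "stewardship", per_day_icu_cost=PER_DAY, per_test=PER_TEST
    )
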