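"""Participant-level data model and dataset transformations.

The package analyses a two-arm, individually randomised ICU trial comparing
rapid in-ICU syndromic PCR testing ("intervention") against standard of care
("control") for hospital-acquired / ventilator-associated pneumonia (HAP/VAP).
This module defines the participant record, CSV input/output, the priority
rule merging the two sources of ICU cost (hospital finance-department income
versus trial-collected bed days), and the dataset transformations that every
analysis scenario consumes: censoring costs to a post-randomisation day,
excluding high-cost outlier stays, and building complete-case analysis sets.

Conventions
-----------
* Money is in pounds sterling (GBP, pounds not pence), 2020/21 price year.
* Dates are ISO-8601 in CSV files and :class:`datetime.date` in memory.
* Missing optional values are *absent* (``None`` / empty CSV cell), never 0.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

ARMS = ("control", "intervention")
AGE_GROUPS = ("adult", "paediatric")
INFECTION_TYPES = ("HAP", "VAP")
COVID_LEVELS = ("no", "yes", "unknown")
OUTCOMES = ("stewardship", "cure")
COST_DEFINITIONS = ("base_case", "total")

#: Day at which trial-collected ICU stay data are censored.
TRIAL_COLLECTION_CENSOR_DAY = 21


class SchemaError(ValueError):
    """An input file does not have the documented layout."""


class ValidationError(ValueError):
    """Input values violate a documented invariant."""


@dataclass(frozen=True)
class ResourceUse:
    """Counts of routine diagnostics recorded from randomisation to
    day 21 / discharge / death, whichever came first."""

    n_cultures: int = 0
    n_viral_pcr: int = 0
    n_xray: int = 0
    n_ct: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cultures", "n_viral_pcr", "n_xray", "n_ct"):
            v = getattr(self, name)
            if v is None or v < 0 or int(v) != v:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class AntibioticCourse:
    """One prescribed antibiotic course (name, dose, frequency, route, span)."""

    drug_name: str
    dose: str
    frequency_per_day: float
    route: str  # oral | intravenous | other
    start: _dt.datetime
    end: _dt.datetime

    def __post_init__(self) -> None:
        if self.frequency_per_day <= 0:
            raise ValidationError("frequency_per_day must be positive")
        if self.route not in ("oral", "intravenous", "other"):
            raise ValidationError(f"unknown route {self.route!r}")
        if self.start > self.end:
            raise ValidationError("antibiotic course start must be <= end")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.drug_name, self.dose, self.route)


@dataclass
class ParticipantRecord:
    """One randomised participant with covariates, outcomes, costs and
    resource use.

    ``finance_icu_cost`` is the finance-department income for the contiguous
    ICU stay from randomisation (the preferred cost source).
    ``finance_total_admission_cost`` is the whole-admission income (all ICU
    stays plus general ward stays). ``trial_icu_days`` is the trial-collected
    ICU stay length, censored at day 21, used when finance data are absent.
    """

    participant_id: str
    site_id: str
    arm: str
    age_group: str = "adult"
    infection_type: str = "VAP"
    covid_baseline: str = "no"
    sofa_score: Optional[float] = None
    other_infection: str = "no"
    stewardship_24h: Optional[str] = None  # success | failure | None
    cure_14d: Optional[str] = None         # cured | not_cured | None
    death_28d: Optional[str] = None        # dead | alive | None
    randomisation_date: Optional[_dt.date] = None
    icu_discharge_date: Optional[_dt.date] = None
    finance_icu_cost: Optional[float] = None
    finance_total_admission_cost: Optional[float] = None
    trial_icu_days: Optional[float] = None
    resource_use: ResourceUse = field(default_factory=ResourceUse)
    antibiotic_courses: list[AntibioticCourse] = field(default_factory=list)
    panel_tests_performed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"unknown age_group {self.age_group!r}")
        if self.infection_type not in INFECTION_TYPES:
            raise ValidationError(f"unknown infection_type {self.infection_type!r}")
        if self.covid_baseline not in COVID_LEVELS:
            raise ValidationError(f"unknown covid_baseline {self.covid_baseline!r}")
        if self.arm == "control" and self.panel_tests_performed != 0:
            raise ValidationError(
                f"{self.participant_id}: control-arm records cannot have panel tests"
            )
        if self.panel_tests_performed < 0:
            raise ValidationError("panel_tests_performed must be >= 0")
        if self.sofa_score is not None and self.sofa_score < 0:
            raise ValidationError("sofa_score must be non-negative")
        if self.trial_icu_days is not None:
            if self.trial_icu_days < 0:
                raise ValidationError("trial_icu_days must be non-negative")
            if self.trial_icu_days > TRIAL_COLLECTION_CENSOR_DAY:
                raise ValidationError(
                    f"trial_icu_days exceeds the day-{TRIAL_COLLECTION_CENSOR_DAY} "
                    "collection window"
                )
        if (
            self.randomisation_date is not None
            and self.icu_discharge_date is not None
            and self.icu_discharge_date < self.randomisation_date
        ):
            raise ValidationError(
                f"{self.participant_id}: ICU discharge precedes randomisation"
            )
        if self.finance_icu_cost is not None and self.finance_icu_cost < 0:
            raise ValidationError("finance_icu_cost must be non-negative")

    def stay_days(self) -> Optional[float]:
        """ICU stay length from randomisation, in whole days (minimum 1).

        Computed from the half-open interval randomisation -> discharge when
        both dates are present; falls back to the trial-collected day count.
        Same-day discharge counts as one day so that per-day cost rates are
        always well defined.
        """
        if self.randomisation_date is not None and self.icu_discharge_date is not None:
            return float(max(1, (self.icu_discharge_date - self.randomisation_date).days))
        if self.trial_icu_days is not None:
            return float(max(1.0, self.trial_icu_days))
        return None


# ---------------------------------------------------------------------------
# CSV input / output

CSV_COLUMNS = [
    "participant_id", "site_id", "arm", "age_group", "infection_type",
    "covid_baseline", "sofa_score", "other_infection", "stewardship_24h",
    "cure_14d", "death_28d", "randomisation_date", "icu_discharge_date",
    "finance_icu_cost", "finance_total_admission_cost", "trial_icu_days",
    "n_cultures", "n_viral_pcr", "n_xray", "n_ct", "panel_tests_performed",
]

ANTIBIOTIC_CSV_COLUMNS = [
    "participant_id", "drug_name", "dose", "frequency_per_day", "route",
    "start", "end",
]


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return str(value)


def _opt_date(value) -> Optional[_dt.date]:
    s = _opt_str(value)
    if s is None:
        return None
    try:
        return _dt.date.fromisoformat(s[:10])
    except ValueError:
        return None


def read_participants(path, antibiotics_path=None) -> list[ParticipantRecord]:
    """Read the participants CSV (and optional antibiotic-course CSV).

    Unparseable *optional* fields become absent, not zero. Raises
    :class:`SchemaError` naming any missing mandatory column and
    :class:`ValidationError` on duplicated participant ids.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"participants CSV is missing column(s): {', '.join(missing)}")
    dup = df["participant_id"][df["participant_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate participant_id(s): {sorted(set(dup))}")

    courses_by_id: dict[str, list[AntibioticCourse]] = {}
    if antibiotics_path is not None:
        adf = pd.read_csv(antibiotics_path, dtype=str, keep_default_na=False)
        a_missing = [c for c in ANTIBIOTIC_CSV_COLUMNS if c not in adf.columns]
        if a_missing:
            raise SchemaError(
                f"antibiotics CSV is missing column(s): {', '.join(a_missing)}"
            )
        for row in adf.itertuples(index=False):
            course = AntibioticCourse(
                drug_name=row.drug_name,
                dose=row.dose,
                frequency_per_day=float(row.frequency_per_day),
                route=row.route,
                start=_dt.datetime.fromisoformat(row.start),
                end=_dt.datetime.fromisoformat(row.end),
            )
            courses_by_id.setdefault(row.participant_id, []).append(course)

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        rec = ParticipantRecord(
            participant_id=d["participant_id"],
            site_id=d["site_id"],
            arm=d["arm"],
            age_group=d["age_group"],
            infection_type=d["infection_type"],
            covid_baseline=d["covid_baseline"],
            sofa_score=_opt_float(d["sofa_score"]),
            other_infection=d["other_infection"],
            stewardship_24h=_opt_str(d["stewardship_24h"]),
            cure_14d=_opt_str(d["cure_14d"]),
            death_28d=_opt_str(d["death_28d"]),
            randomisation_date=_opt_date(d["randomisation_date"]),
            icu_discharge_date=_opt_date(d["icu_discharge_date"]),
            finance_icu_cost=_opt_float(d["finance_icu_cost"]),
            finance_total_admission_cost=_opt_float(d["finance_total_admission_cost"]),
            trial_icu_days=_opt_float(d["trial_icu_days"]),
            resource_use=ResourceUse(
                n_cultures=int(_opt_float(d["n_cultures"]) or 0),
                n_viral_pcr=int(_opt_float(d["n_viral_pcr"]) or 0),
                n_xray=int(_opt_float(d["n_xray"]) or 0),
                n_ct=int(_opt_float(d["n_ct"]) or 0),
            ),
            antibiotic_courses=courses_by_id.get(d["participant_id"], []),
            panel_tests_performed=int(_opt_float(d["panel_tests_performed"]) or 0),
        )
        records.append(rec)
    return records


def participants_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame with the documented CSV layout."""
    rows = []
    for r in records:
        rows.append({
            "participant_id": r.participant_id,
            "site_id": r.site_id,
            "arm": r.arm,
            "age_group": r.age_group,
            "infection_type": r.infection_type,
            "covid_baseline": r.covid_baseline,
            "sofa_score": r.sofa_score,
            "other_infection": r.other_infection,
            "stewardship_24h": r.stewardship_24h,
            "cure_14d": r.cure_14d,
            "death_28d": r.death_28d,
            "randomisation_date": r.randomisation_date.isoformat() if r.randomisation_date else None,
            "icu_discharge_date": r.icu_discharge_date.isoformat() if r.icu_discharge_date else None,
            "finance_icu_cost": r.finance_icu_cost,
            "finance_total_admission_cost": r.finance_total_admission_cost,
            "trial_icu_days": r.trial_icu_days,
            "n_cultures": r.resource_use.n_cultures,
            "n_viral_pcr": r.resource_use.n_viral_pcr,
            "n_xray": r.resource_use.n_xray,
            "n_ct": r.resource_use.n_ct,
            "panel_tests_performed": r.panel_tests_performed,
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_participants(records, path, antibiotics_path=None) -> None:
    """Write records (and optionally their antibiotic courses) to CSV."""
    participants_to_frame(records).to_csv(path, index=False)
    if antibiotics_path is not None:
        rows = []
        for r in records:
            for c in r.antibiotic_courses:
                rows.append({
                    "participant_id": r.participant_id,
                    "drug_name": c.drug_name,
                    "dose": c.dose,
                    "frequency_per_day": c.frequency_per_day,
                    "route": c.route,
                    "start": c.start.isoformat(),
                    "end": c.end.isoformat(),
                })
        pd.DataFrame(rows, columns=ANTIBIOTIC_CSV_COLUMNS).to_csv(antibiotics_path, index=False)


# ---------------------------------------------------------------------------
# Cost-source merging

def merge_cost_sources(
    record: ParticipantRecord, per_day_icu_cost: float
) -> tuple[Optional[float], str]:
    """Resolve the ICU cost for one participant.

    Finance-department income is the preferred source; where unavailable the
    censored trial-collected stay is valued at ``per_day_icu_cost``. Returns
    ``(cost, source)`` where source is ``"finance"``, ``"trial_collected"``
    or ``"unresolved"`` (cost ``None``).
    """
    if per_day_icu_cost <= 0:
        raise ValidationError("per_day_icu_cost must be positive")
    if record.finance_icu_cost is not None:
        return float(record.finance_icu_cost), "finance"
    if record.trial_icu_days is not None:
        return float(record.trial_icu_days) * per_day_icu_cost, "trial_collected"
    return None, "unresolved"


# ---------------------------------------------------------------------------
# Analysis datasets

_OUTCOME_CODING = {
    "stewardship": ("stewardship_24h", {"success": 1, "failure": 0}),
    "cure": ("cure_14d", {"cured": 1, "not_cured": 0}),
}

#: Table columns of :class:`AnalysisDataset`.
ANALYSIS_COLUMNS = [
    "participant_id", "site_id", "arm", "arm_ind", "age_group",
    "infection_type", "covid_baseline", "sofa_score", "other_infection",
    "outcome", "icu_cost", "stay_days", "cost_source", "panel_cost", "cost",
]


@dataclass
class AnalysisDataset:
    """A complete-case analysis set: one row per costed participant with a
    non-missing outcome, an intention-to-treat arm label, a resolved cost and
    its provenance flag.

    ``cost`` is the analysis cost under ``cost_definition``:
    base case = resolved ICU cost + panel cost (intervention only);
    total = whole-admission income + panel cost.
    """

    table: pd.DataFrame
    outcome_name: str
    cost_definition: str
    per_day_icu_cost: float
    exclusions: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_control(self) -> int:
        return int((self.table["arm"] == "control").sum())

    @property
    def n_intervention(self) -> int:
        return int((self.table["arm"] == "intervention").sum())

    @property
    def n_sites(self) -> int:
        return int(self.table["site_id"].nunique())

    def costs_by_arm(self) -> tuple[np.ndarray, np.ndarray]:
        t = self.table
        return (
            t.loc[t["arm"] == "control", "cost"].to_numpy(float),
            t.loc[t["arm"] == "intervention", "cost"].to_numpy(float),
        )


def build_analysis_dataset(
    records: Sequence[ParticipantRecord],
    outcome_name: str,
    cost_definition: str = "base_case",
    *,
    per_day_icu_cost: float,
    per_test: float,
    finance_only: bool = False,
) -> AnalysisDataset:
    """Construct the complete-case analysis set for one outcome and cost
    definition.

    Records missing the chosen outcome, with unresolved ICU cost, or (for the
    total-cost definition) without whole-admission finance data are dropped
    and counted in ``exclusions``. Arm is as randomised (intention to treat).
    """
    if outcome_name not in OUTCOMES:
        raise ValueError(f"outcome_name must be one of {OUTCOMES}")
    if cost_definition not in COST_DEFINITIONS:
        raise ValueError(f"cost_definition must be one of {COST_DEFINITIONS}")

    col, coding = _OUTCOME_CODING[outcome_name]
    exclusions = {
        "missing_outcome": 0,
        "unresolved_cost": 0,
        "missing_total_cost": 0,
        "non_finance_source": 0,
    }
    rows = []
    for r in records:
        raw = getattr(r, col)
        if raw not in coding:
            exclusions["missing_outcome"] += 1
            continue
        icu_cost, source = merge_cost_sources(r, per_day_icu_cost)
        if source == "unresolved":
            exclusions["unresolved_cost"] += 1
            continue
        if finance_only and source != "finance":
            exclusions["non_finance_source"] += 1
            continue
        panel_cost = r.panel_tests_performed * per_test if r.arm == "intervention" else 0.0
        if cost_definition == "total":
            if r.finance_total_admission_cost is None:
                exclusions["missing_total_cost"] += 1
                continue
            cost = r.finance_total_admission_cost + panel_cost
        else:
            cost = icu_cost + panel_cost
        rows.append({
            "participant_id": r.participant_id,
            "site_id": r.site_id,
            "arm": r.arm,
            "arm_ind": 1 if r.arm == "intervention" else 0,
            "age_group": r.age_group,
            "infection_type": r.infection_type,
            "covid_baseline": r.covid_baseline,
            "sofa_score": r.sofa_score,
            "other_infection": r.other_infection,
            "outcome": coding[raw],
            "icu_cost": icu_cost,
            "stay_days": r.stay_days(),
            "cost_source": source,
            "panel_cost": panel_cost,
            "cost": cost,
        })
    table = pd.DataFrame(rows, columns=ANALYSIS_COLUMNS)
    counts = table["arm"].value_counts()
    if counts.get("control", 0) < 1 or counts.get("intervention", 0) < 1:
        raise ValidationError(
            f"analysis dataset for {outcome_name!r} has an empty arm after exclusions"
        )
    return AnalysisDataset(
        table=table,
        outcome_name=outcome_name,
        cost_definition=cost_definition,
        per_day_icu_cost=per_day_icu_cost,
        exclusions=exclusions,
    )


def censor_to_day(dataset: AnalysisDataset, day: int) -> AnalysisDataset:
    """Truncate each participant's ICU cost to the first ``day`` days.

    Finance costs are lump sums, so each stay's cost is converted to a
    uniform daily rate over the contiguous stay and the first ``day`` days
    are kept: censored cost = cost * min(stay, day) / stay. Stays at or below
    ``day`` are unchanged; stay lengths are truncated alongside so the
    operation is idempotent. Stays of unknown length are left unchanged.
    """
    if day < 1:
        raise ValueError("censor day must be >= 1")
    if dataset.cost_definition != "base_case":
        raise ValueError("day-censoring is defined for base-case ICU costs only")
    t = dataset.table.copy()
    stay = t["stay_days"].to_numpy(float)
    known = ~np.isnan(stay)
    frac = np.ones(len(t))
    frac[known] = np.minimum(stay[known], day) / stay[known]
    t["icu_cost"] = t["icu_cost"].to_numpy(float) * frac
    t["stay_days"] = np.where(known, np.minimum(stay, day), stay)
    t["cost"] = t["icu_cost"] + t["panel_cost"]
    return replace(dataset, table=t)


def exclude_cost_outliers(dataset: AnalysisDataset, threshold: float) -> AnalysisDataset:
    """Drop participants whose resolved ICU stay cost strictly exceeds
    ``threshold`` (a stay costing exactly the threshold is retained)."""
    if threshold <= 0:
        raise ValueError("outlier threshold must be positive")
    t = dataset.table
    keep = t["icu_cost"].to_numpy(float) <= threshold
    excl = dict(dataset.exclusions)
    excl["cost_outlier"] = excl.get("cost_outlier", 0) + int((~keep).sum())
    return replace(dataset, table=t.loc[keep].reset_index(drop=True), exclusions=excl)
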