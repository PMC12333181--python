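"""Micro-costing engine.

Implements the NHS secondary-care costing used by the evaluation: equivalent
annual cost (EAC) annuitization of the PCR instrument, cost per panel test,
per-person panel cost in the intervention arm, discounting of costs accruing
beyond one year, unit-costing of routine diagnostics and antibiotic
acquisition, and the base-case / total cost aggregations.

Base-case analysis cost = resolved ICU-stay cost from randomisation plus the
panel cost for intervention participants. Routine-test and antibiotic costs
are *not* added on top: within the NHS income data they are already embedded
in the ICU per-day cost, so adding them would double count. "Total" cost
replaces the contiguous ICU stay with the whole-admission income (all ICU
stays plus general ward stays).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .trial_data import (
    AntibioticCourse,
    ParticipantRecord,
    ResourceUse,
    SchemaError,
    ValidationError,
    merge_cost_sources,
)

#: Published per-test cost of the pneumonia panel (GBP). A calibration
#: output whose underlying price quotes are confidential, carried here as a
#: configuration default rather than derived from a price decomposition.
DEFAULT_PER_TEST_COST = 196.0

#: Annual discount / interest rate used for annuitization and for costs
#: accruing beyond one year.
DEFAULT_DISCOUNT_RATE = 0.035


@dataclass(frozen=True)
class DeviceCostInputs:
    """Inputs for annuitizing the PCR instrument and costing one test.

    Defaults mirror the evaluation's assumptions: 5-year operational life,
    3.5 % interest, no resale value, 360 tests/year per instrument, five
    minutes of band 6 nurse time per test. Monetary inputs (purchase price,
    consumables, QC, staff rate, leasing) are user configuration.
    """

    purchase_price: float
    lifetime_years: int = 5
    interest_rate: float = DEFAULT_DISCOUNT_RATE
    resale_value: float = 0.0
    annual_throughput_tests: int = 360
    consumable_cost_per_test: float = 0.0
    qc_cost_per_test: float = 0.0
    staff_minutes_per_test: float = 5.0
    staff_cost_per_minute: float = 0.0
    leasing_annual_cost: Optional[float] = None

    def __post_init__(self) -> None:
        if self.interest_rate < 0:
            raise ValidationError("interest_rate must be >= 0")
        if self.lifetime_years < 1:
            raise ValidationError("lifetime_years must be >= 1")
        if self.annual_throughput_tests < 1:
            raise ValidationError("annual_throughput_tests must be >= 1")
        if self.staff_minutes_per_test < 0:
            raise ValidationError("staff_minutes_per_test must be >= 0")


@dataclass
class UnitCostTable:
    """Unit costs for routine diagnostics and an antibiotic price list.

    Diagnostic defaults are the evaluation's NHS reference / expert-opinion
    costs: £20 per microbiological culture, £40 per in-house respiratory
    viral PCR, £45 per chest X-ray, £144 per CT scan. Antibiotic prices are
    per administration, keyed by (drug, dose, route).
    """

    culture: float = 20.0
    viral_pcr: float = 40.0
    xray: float = 45.0
    ct: float = 144.0
    antibiotic_prices: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("culture", "viral_pcr", "xray", "ct"):
            if getattr(self, name) < 0:
                raise ValidationError(f"unit cost {name} must be >= 0")


def read_unit_costs(path) -> UnitCostTable:
    """Read the unit-cost CSV (columns: item, name, unit_cost_gbp).

    Diagnostic rows have ``item`` in {culture, viral_pcr, xray, ct}; for
    antibiotic rows ``item`` is ``antibiotic`` and ``name`` is
    ``drug|dose|route``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("item", "name", "unit_cost_gbp"):
        if col not in df.columns:
            raise SchemaError(f"unit-cost CSV is missing column: {col}")
    kwargs: dict = {}
    prices: dict[tuple[str, str, str], float] = {}
    for row in df.itertuples(index=False):
        cost = float(row.unit_cost_gbp)
        if row.item == "antibiotic":
            parts = row.name.split("|")
            if len(parts) != 3:
                raise SchemaError(
                    f"antibiotic name must be 'drug|dose|route', got {row.name!r}"
                )
            prices[tuple(parts)] = cost
        elif row.item in ("culture", "viral_pcr", "xray", "ct"):
            kwargs[row.item] = cost
        else:
            raise SchemaError(f"unknown unit-cost item {row.item!r}")
    return UnitCostTable(antibiotic_prices=prices, **kwargs)


def write_unit_costs(table: UnitCostTable, path) -> None:
    rows = [
        {"item": item, "name": item, "unit_cost_gbp": getattr(table, item)}
        for item in ("culture", "viral_pcr", "xray", "ct")
    ]
    for (drug, dose, route), cost in sorted(table.antibiotic_prices.items()):
        rows.append({"item": "antibiotic", "name": f"{drug}|{dose}|{route}",
                     "unit_cost_gbp": cost})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Annuitization and discounting

def annuity_factor(rate: float, years: int) -> float:
    """Present value of a unit payment at the end of each of ``years`` years.

    (1 - (1+rate)^-years) / rate for rate > 0; equals ``years`` in the
    zero-interest limit.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if years < 1:
        raise ValueError("years must be >= 1")
    if rate == 0:
        return float(years)
    # -expm1(-n*log1p(r))/r == (1-(1+r)^-n)/r, stable as r -> 0
    return -math.expm1(-years * math.log1p(rate)) / rate


def equivalent_annual_cost(inputs: DeviceCostInputs) -> float:
    """Annuitize the instrument's net purchase cost over its lifetime.

    EAC = (price - resale * (1+r)^-L) / annuity_factor(r, L); with zero
    resale and zero interest this is straight-line price / lifetime.
    """
    r, years = inputs.interest_rate, inputs.lifetime_years
    npv = inputs.purchase_price - inputs.resale_value * (1.0 + r) ** (-years)
    return npv / annuity_factor(r, years)


def cost_per_test(inputs: DeviceCostInputs, mode: str = "purchase") -> float:
    """Total cost of one panel test: annualised equipment cost spread over
    annual throughput, plus consumables, quality control, and nurse time."""
    if mode == "purchase":
        annual = equivalent_annual_cost(inputs)
    elif mode == "lease":
        if inputs.leasing_annual_cost is None:
            raise ValueError("lease mode requires leasing_annual_cost")
        annual = inputs.leasing_annual_cost
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return (
        annual / inputs.annual_throughput_tests
        + inputs.consumable_cost_per_test
        + inputs.qc_cost_per_test
        + inputs.staff_minutes_per_test * inputs.staff_cost_per_minute
    )


def discount_beyond_one_year(cost: float, years_after_randomisation: float,
                             rate: float = DEFAULT_DISCOUNT_RATE) -> float:
    """Discount a cost accruing ``years_after_randomisation`` years out.

    Costs within the first year are taken at face value; beyond one year the
    excess horizon is discounted at annual compounding:
    cost * (1+rate)^-(years-1).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if years_after_randomisation < 0:
        raise ValueError("years_after_randomisation must be >= 0")
    if years_after_randomisation <= 1.0:
        return cost
    return cost * (1.0 + rate) ** (-(years_after_randomisation - 1.0))


# ---------------------------------------------------------------------------
# Panel, resource-use and antibiotic costs

def per_person_panel_cost(records: Iterable[ParticipantRecord],
                          per_test: float = DEFAULT_PER_TEST_COST) -> float:
    """Mean panel cost per intervention-arm participant.

    Each participant contributes panel_tests_performed * per_test; repeat
    tests after failures push the per-person mean above the per-test cost.
    Control-arm participants always cost 0 and are ignored here.
    """
    costs = [
        r.panel_tests_performed * per_test
        for r in records
        if r.arm == "intervention"
    ]
    if not costs:
        raise ValidationError("no intervention-arm participants to cost")
    return float(sum(costs) / len(costs))


def resource_use_cost(use: ResourceUse, table: UnitCostTable) -> float:
    """Unit-costed routine diagnostics (cultures, viral PCR, X-ray, CT)."""
    return (
        use.n_cultures * table.culture
        + use.n_viral_pcr * table.viral_pcr
        + use.n_xray * table.xray
        + use.n_ct * table.ct
    )


def antibiotic_acquisition_cost(
    courses: Sequence[AntibioticCourse], table: UnitCostTable
) -> tuple[float, list[tuple[str, str, str]]]:
    """Acquisition cost of antibiotic courses (administration/monitoring
    costs are out of scope).

    Administrations per course = frequency_per_day * ceil(duration in days),
    with a minimum of one administration (a course recorded with start = end
    reflects at least one dose). Returns ``(total, unpriced)`` where
    ``unpriced`` lists (drug, dose, route) keys absent from the price table;
    unpriced courses are reported, never silently zero-costed.
    """
    total = 0.0
    unpriced: list[tuple[str, str, str]] = []
    for course in courses:
        price = table.antibiotic_prices.get(course.key)
        if price is None:
            unpriced.append(course.key)
            continue
        days = (course.end - course.start).total_seconds() / 86400.0
        administrations = max(1.0, course.frequency_per_day * math.ceil(days))
        total += administrations * price
    return total, unpriced


# ---------------------------------------------------------------------------
# Aggregations

def base_case_cost(record: ParticipantRecord, icu_cost: float,
                   per_test: float = DEFAULT_PER_TEST_COST) -> float:
    """Base-case analysis cost: contiguous ICU stay from randomisation plus
    panel cost (intervention arm only). Routine tests and antibiotics are
    excluded to avoid double counting within the ICU income."""
    panel = record.panel_tests_performed * per_test if record.arm == "intervention" else 0.0
    return icu_cost + panel


def total_cost(record: ParticipantRecord,
               per_test: float = DEFAULT_PER_TEST_COST) -> Optional[float]:
    """Total analysis cost: whole-admission income (all ICU stays + general
    wards) plus panel cost. ``None`` when whole-admission finance data are
    absent (such records are excluded from total-cost scenarios)."""
    if record.finance_total_admission_cost is None:
        return None
    panel = record.panel_tests_performed * per_test if record.arm == "intervention" else 0.0
    return record.finance_total_admission_cost + panel


def participant_cost_breakdown(
    records: Sequence[ParticipantRecord],
    unit_costs: UnitCostTable,
    *,
    per_day_icu_cost: float,
    per_test: float = DEFAULT_PER_TEST_COST,
) -> pd.DataFrame:
    """Per-participant component costs (one row each): resolved ICU cost and
    its source, panel, routine diagnostics, antibiotics, base-case and total
    aggregates. Component columns for diagnostics/antibiotics are
    informational; they are not part of the base case."""
    rows = []
    for r in records:
        icu_cost, source = merge_cost_sources(r, per_day_icu_cost)
        abx_cost, unpriced = antibiotic_acquisition_cost(r.antibiotic_courses, unit_costs)
        panel = r.panel_tests_performed * per_test if r.arm == "intervention" else 0.0
        use = r.resource_use
        rows.append({
            "participant_id": r.participant_id,
            "site_id": r.site_id,
            "arm": r.arm,
            "icu_cost": icu_cost,
            "cost_source": source,
            "panel_cost": panel,
            "culture_viral_pcr_cost": use.n_cultures * unit_costs.culture
            + use.n_viral_pcr * unit_costs.viral_pcr,
            "xray_cost": use.n_xray * unit_costs.xray,
            "ct_cost": use.n_ct * unit_costs.ct,
            "resource_cost": resource_use_cost(r.resource_use, unit_costs),
            "antibiotic_cost": abx_cost,
            "n_unpriced_courses": len(unpriced),
            "base_case_cost": None if icu_cost is None else base_case_cost(r, icu_cost, per_test),
            "total_cost": total_cost(r, per_test),
        })
    return pd.DataFrame(rows)
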