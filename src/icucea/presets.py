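"""Default configuration objects and config-file I/O.

The diagnostic unit costs are the evaluation's NHS reference / expert
figures; the antibiotic price list and the device-cost decomposition are
synthetic placeholders (the real instrument prices are confidential), so
the per-test panel cost used downstream defaults to the published £196
rather than being derived from the example device config.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .costing import DeviceCostInputs, UnitCostTable
from .synthetic_trial import SYNTHETIC_FORMULARY, SimulationConfig

#: Daily ICU rate used to value trial-collected (day-censored) stays when
#: finance-department data are absent. The source evaluation does not state
#: its rate; £2,000/day is a mid-range NHS adult critical-care cost and is
#: exposed in configuration.
DEFAULT_PER_DAY_ICU_COST = 2000.0


def default_unit_costs() -> UnitCostTable:
    """Diagnostic unit costs plus the synthetic antibiotic formulary."""
    return UnitCostTable(antibiotic_prices={
        (drug, dose, route): price
        for drug, dose, route, price in SYNTHETIC_FORMULARY
    })


def example_device_inputs() -> DeviceCostInputs:
    """A synthetic, illustrative device-cost decomposition (the real price
    quotes are unpublished). Yields a cost per test of ~£181."""
    return DeviceCostInputs(
        purchase_price=30_000.0,
        lifetime_years=5,
        interest_rate=0.035,
        resale_value=0.0,
        annual_throughput_tests=360,
        consumable_cost_per_test=150.0,
        qc_cost_per_test=10.0,
        staff_minutes_per_test=5.0,
        staff_cost_per_minute=0.50,
    )


def read_device_config(path) -> DeviceCostInputs:
    """Load device-cost inputs from a YAML/JSON mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return DeviceCostInputs(**data)


def write_device_config(inputs: DeviceCostInputs, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(inputs), fh, sort_keys=False)


def read_simulation_config(path, **overrides) -> SimulationConfig:
    """Load a simulation config from YAML/JSON, applying overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return SimulationConfig(**data)
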