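"""Report rendering: unadjusted cost tables, CE-plane and CEAC figures,
and run manifests.

The unadjusted table mirrors the conventional trial cost-breakdown layout
(per-arm mean and SD per component, difference in means with a Welch 95 %
CI); figures follow the standard presentation of within-trial economic
evaluations — CE-plane scatter with zero axes, CEAC probability curves over
the willingness-to-pay grid.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional, Sequence

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import __version__
from .costing import UnitCostTable, participant_cost_breakdown
from .estimation import unadjusted_mean_difference
from .trial_data import ParticipantRecord

COMPONENT_ORDER = [
    ("panel_cost", "Pneumonia panel"),
    ("icu_cost", "ICU (from randomisation)"),
    ("culture_viral_pcr_cost", "Microbiological culture & viral PCR"),
    ("antibiotic_cost", "Antimicrobials"),
    ("xray_cost", "X-ray"),
    ("ct_cost", "CT"),
    ("base_case_cost", "Base case: panel + ICU"),
    ("total_cost", "Total: panel + whole admission"),
]


def unadjusted_cost_table(
    records: Sequence[ParticipantRecord],
    unit_costs: UnitCostTable,
    *,
    per_day_icu_cost: float,
    per_test: float,
) -> pd.DataFrame:
    """Unadjusted per-arm cost breakdown with differences in means.

    One row per component; columns give per-arm N, mean and SD, the
    intervention-minus-control difference and its Welch 95 % CI. Components
    with missing values (unresolved ICU cost, absent whole-admission data)
    use the per-component complete cases, so N can differ across rows.
    """
    bd = participant_cost_breakdown(
        records, unit_costs, per_day_icu_cost=per_day_icu_cost, per_test=per_test
    )
    rows = []
    for col, label in COMPONENT_ORDER:
        sub = bd[~bd[col].isna()]
        c = sub.loc[sub["arm"] == "control", col].to_numpy(float)
        i = sub.loc[sub["arm"] == "intervention", col].to_numpy(float)
        row = {
            "component": label,
            "control_n": len(c), "intervention_n": len(i),
            "control_mean": c.mean() if len(c) else np.nan,
            "control_sd": c.std(ddof=1) if len(c) > 1 else np.nan,
            "intervention_mean": i.mean() if len(i) else np.nan,
            "intervention_sd": i.std(ddof=1) if len(i) > 1 else np.nan,
        }
        if len(c) >= 2 and len(i) >= 2 and (c.std() > 0 or i.std() > 0):
            est = unadjusted_mean_difference(c, i)
            row.update(diff=est.point, ci_low=est.ci_low, ci_high=est.ci_high)
        else:
            row.update(
                diff=row["intervention_mean"] - row["control_mean"]
                if len(c) and len(i) else np.nan,
                ci_low=np.nan, ci_high=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Figures

def plot_ce_plane(draws: pd.DataFrame, path, title: Optional[str] = None) -> None:
    """CE-plane scatter (Δeffect on x, Δcost on y) with zero axes; one panel
    per scenario present in the draws frame."""
    scenarios = list(draws["scenario"].unique())
    fig, axes = plt.subplots(
        1, max(len(scenarios), 1), figsize=(4.2 * max(len(scenarios), 1), 4),
        squeeze=False,
    )
    for ax, scen in zip(axes[0], scenarios):
        sub = draws[draws["scenario"] == scen]
        ax.scatter(sub["delta_effect"], sub["delta_cost"], s=6, alpha=0.4)
        ax.axhline(0.0, color="black", lw=0.8)
        ax.axvline(0.0, color="black", lw=0.8)
        ax.set_xlabel("Incremental effect (proportion)")
        ax.set_ylabel("Incremental cost (GBP)")
        ax.set_title(scen)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curves: pd.DataFrame, path, title: Optional[str] = None) -> None:
    """CEAC line chart: probability cost-effective vs willingness to pay,
    one line per scenario."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for scen, sub in curves.groupby("scenario", sort=False):
        ax.plot(sub["wtp"], sub["prob_cost_effective"], label=scen)
    ax.set_xlabel("Willingness to pay (GBP per 1% effect)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Manifests

def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(path, *, command: str, seed: Optional[int], config: dict,
                   extra: Optional[dict] = None) -> None:
    """Record how a run was produced: command, seed, config hash and full
    config, package/library versions, plus run-specific counts."""
    import numpy
    import pandas
    import statsmodels

    manifest = {
        "command": command,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "versions": {
            "icucea": __version__,
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
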