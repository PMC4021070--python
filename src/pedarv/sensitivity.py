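"""Sensitivity of age-based drug costs to the population weight adjustment.

The baseline analysis relocates the growth reference to z = -1.5 with the
general population's coefficient of variation.  This module re-runs the
band-probability and age-costing pipeline for alternative adjustments
(z-shifts between -3 and 0; CV halved or doubled) and summarizes, for each
variant, the mean absolute percentage change across all drug-by-age cells
relative to baseline.  Cells that are undefined at baseline (not
recommended, or zero cost) are excluded from the mean and counted
explicitly — the summary never silently averages over them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .cost_engine import (
    DAYS_PER_MONTH,
    FormulationStrategy,
    drug_cost_table,
)
from .growth import (
    LMSRecord,
    PAPER_AGE_GRID,
    PopulationAdjustment,
    band_probability_table,
)
from .reference_data import DosingRule, PriceEntry

__all__ = ["SensitivityResult", "sensitivity_scan", "DEFAULT_DRUG_STRATEGIES"]

#: Drug/strategy rows scanned by default: every drug of the age-cost table,
#: under both strategies where formulations overlap.
DEFAULT_DRUG_STRATEGIES: tuple[tuple[str, FormulationStrategy], ...] = (
    ("ABC", FormulationStrategy.LIQUID_FIRST),
    ("ABC", FormulationStrategy.TABLET_FIRST),
    ("d4T", FormulationStrategy.LIQUID_FIRST),
    ("3TC", FormulationStrategy.LIQUID_FIRST),
    ("EFV", FormulationStrategy.TABLET_FIRST),
    ("LPV/r", FormulationStrategy.LIQUID_FIRST),
    ("LPV/r", FormulationStrategy.TABLET_FIRST),
    ("NVP", FormulationStrategy.LIQUID_FIRST),
    ("NVP", FormulationStrategy.TABLET_FIRST),
    ("ZDV", FormulationStrategy.LIQUID_FIRST),
    ("ZDV", FormulationStrategy.TABLET_FIRST),
    ("ZDV/3TC", FormulationStrategy.TABLET_FIRST),
    ("ZDV/3TC/NVP", FormulationStrategy.TABLET_FIRST),
    ("d4T/3TC", FormulationStrategy.TABLET_FIRST),
    ("d4T/3TC/NVP", FormulationStrategy.TABLET_FIRST),
    ("ABC/3TC", FormulationStrategy.TABLET_FIRST),
)


@dataclass(frozen=True)
class SensitivityResult:
    """Deviation of one adjustment variant from the baseline costs."""

    adjustment: PopulationAdjustment
    mean_abs_pct_change: float
    n_cells: int
    n_excluded: int
    changes: pd.DataFrame  # long format: drug, strategy, age_years, pct_change

    def __post_init__(self) -> None:
        assert self.mean_abs_pct_change >= 0


def _cost_grid(adj: PopulationAdjustment,
               lms_table: Sequence[LMSRecord],
               dosing: Sequence[DosingRule],
               prices: Sequence[PriceEntry],
               drug_strategies: Sequence[tuple[str, FormulationStrategy]],
               ages: Sequence[float],
               days_per_month: float) -> dict[tuple[str, str, float], Optional[float]]:
    probs = band_probability_table(lms_table, adj, ages)
    table = drug_cost_table(drug_strategies, probs, dosing, prices,
                            days_per_month)
    grid: dict[tuple[str, str, float], Optional[float]] = {}
    for (drug, strategy), row in table.items():
        for probs_row, cost in zip(probs, row):
            grid[(drug, strategy.value, probs_row.age_years)] = (
                None if cost is None else cost.monthly_cost)
    return grid


def sensitivity_scan(baseline: PopulationAdjustment,
                     variants: Sequence[PopulationAdjustment],
                     lms_table: Sequence[LMSRecord],
                     dosing: Sequence[DosingRule],
                     prices: Sequence[PriceEntry],
                     drug_strategies: Sequence[tuple[str, FormulationStrategy]] = DEFAULT_DRUG_STRATEGIES,
                     ages: Sequence[float] = PAPER_AGE_GRID,
                     days_per_month: float = DAYS_PER_MONTH,
                     ) -> list[SensitivityResult]:
    """Mean absolute percentage cost change of each variant vs baseline.

    For every (drug, strategy, age) cell defined at baseline and under the
    variant, the percentage change |c_v - c_b| / c_b * 100 is recorded; the
    summary is the mean over those cells.  Cells undefined (NR) or zero at
    baseline, or undefined under the variant, are excluded and counted.
    """
    if not variants:
        raise ValueError("variants must be nonempty")
    if not drug_strategies:
        raise ValueError("drug/strategy set must be nonempty")
    base = _cost_grid(baseline, lms_table, dosing, prices, drug_strategies,
                      ages, days_per_month)
    results = []
    for adj in variants:
        var = _cost_grid(adj, lms_table, dosing, prices, drug_strategies,
                         ages, days_per_month)
        records = []
        n_excluded = 0
        for key, c_base in base.items():
            c_var = var[key]
            if c_base is None or c_base == 0.0 or c_var is None:
                n_excluded += 1
                continue
            drug, strategy, age = key
            records.append({
                "drug": drug, "strategy": strategy, "age_years": age,
                "cost_baseline": c_base, "cost_variant": c_var,
                "pct_change": abs(c_var - c_base) / c_base * 100.0,
            })
        changes = pd.DataFrame(records)
        mean_change = float(changes["pct_change"].mean()) if records else 0.0
        results.append(SensitivityResult(
            adjustment=adj,
            mean_abs_pct_change=mean_change,
            n_cells=len(records),
            n_excluded=n_excluded,
            changes=changes,
        ))
    return results
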