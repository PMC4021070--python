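"""Three-drug regimen costing under formulation-availability scenarios.

A first-line pediatric regimen is an anchor drug (LPV/r, or NVP switching to
EFV at age three) plus an NRTI backbone pair.  Its monthly cost at an age is
the sum of the component drugs' probability-weighted age costs, after a
product-selection step that reflects what a given setting can supply:

* **Scenario 1 (no FDCs, late switch)** — single-drug products only; syrups
  for every component until 4 years of age, then tablets as dosing permits.
* **Scenario 2 (no FDCs, early switch)** — as scenario 1 but children move
  to tablets from 6 months of age.
* **Scenario 3 (FDCs, early switch)** — co-formulated pediatric tablets are
  used from birth wherever one exists whose components are a subset of the
  active regimen (triples take precedence over duals over singles);
  the remaining components follow the scenario-2 liquid/tablet schedule.

"Until age X" is strict: liquids are used at ages below X and the age-X row
itself already uses tablets.  Tablet-first resolution falls back to syrup in
bands where the tablet is not recommended, so very small children keep their
liquid LPV/r even after the nominal switch age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .cost_engine import (
    DAYS_PER_MONTH,
    DRUG_MIN_AGE_YEARS,
    AgeCost,
    CostingError,
    FormulationStrategy,
    drug_cost_by_age,
)
from .growth import BandProbabilityRow
from .reference_data import DoseStatus, DosingRule, PriceEntry

__all__ = [
    "Regimen",
    "ScenarioSpec",
    "ProductSelection",
    "RegimenCostRow",
    "SIX_REGIMENS",
    "scenario",
    "active_components",
    "select_products",
    "regimen_cost",
    "regimen_cost_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Regimen:
    """Anchor drug plus two-drug NRTI backbone.

    ``anchor`` is ``"LPV/r"`` or ``"NVP"``; NVP-anchored regimens switch the
    anchor to EFV at the scenario's switch age, so exactly three components
    are active at any age.
    """

    anchor: str
    backbone: tuple[str, str]
    label: str = ""

    def __post_init__(self) -> None:
        if self.anchor not in ("LPV/r", "NVP"):
            raise CostingError(f"unsupported anchor {self.anchor!r}")
        if len(set(self.backbone)) != 2:
            raise CostingError("backbone must be two distinct NRTIs")
        if not self.label:
            object.__setattr__(self, "label",
                               f"{self.anchor}+{'+'.join(self.backbone)}")


#: The six commonly used first-line regimens.
SIX_REGIMENS: tuple[Regimen, ...] = (
    Regimen("LPV/r", ("ZDV", "3TC")),
    Regimen("LPV/r", ("ABC", "3TC")),
    Regimen("LPV/r", ("d4T", "3TC")),
    Regimen("NVP", ("ZDV", "3TC"), label="NVP/EFV+ZDV+3TC"),
    Regimen("NVP", ("ABC", "3TC"), label="NVP/EFV+ABC+3TC"),
    Regimen("NVP", ("d4T", "3TC"), label="NVP/EFV+d4T+3TC"),
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Formulation availability and switching ages for one setting."""

    scenario_id: int
    fdc_available: bool
    liquid_switch_age_years: float
    nvp_to_efv_age_years: float = 3.0

    def __post_init__(self) -> None:
        gate = DRUG_MIN_AGE_YEARS.get("EFV")
        if gate is not None and self.nvp_to_efv_age_years != gate:
            logger.warning(
                "NVP-to-EFV switch age %.1f differs from the EFV minimum age "
                "%.1f; children may be left without a recommended anchor",
                self.nvp_to_efv_age_years, gate,
            )


def scenario(scenario_id: int) -> ScenarioSpec:
    """The three canonical availability scenarios."""
    if scenario_id == 1:
        return ScenarioSpec(1, fdc_available=False, liquid_switch_age_years=4.0)
    if scenario_id == 2:
        return ScenarioSpec(2, fdc_available=False, liquid_switch_age_years=0.5)
    if scenario_id == 3:
        return ScenarioSpec(3, fdc_available=True, liquid_switch_age_years=0.5)
    raise CostingError(f"unknown scenario {scenario_id}")


@dataclass(frozen=True)
class ProductSelection:
    """One product line of a composed regimen: a drug code (possibly a
    co-formulation code such as ``ZDV/3TC``) with the resolution strategy
    used for its single-product tiers."""

    drug_code: str
    strategy: FormulationStrategy
    covers: frozenset[str]


@dataclass(frozen=True)
class RegimenCostRow:
    regimen: Regimen
    scenario: ScenarioSpec
    age_years: float
    monthly_cost: float
    products: tuple[ProductSelection, ...] = field(default=(), compare=False)


def active_components(regimen: Regimen, age_years: float,
                      spec: ScenarioSpec) -> frozenset[str]:
    """Drug codes active at an age (NVP anchors become EFV at the switch age)."""
    anchor = regimen.anchor
    if anchor == "NVP" and age_years >= spec.nvp_to_efv_age_years:
        anchor = "EFV"
    return frozenset({anchor, *regimen.backbone})


def _single_strategy(age_years: float, spec: ScenarioSpec) -> FormulationStrategy:
    if age_years < spec.liquid_switch_age_years:
        return FormulationStrategy.LIQUID_FIRST
    return FormulationStrategy.TABLET_FIRST


def _fdc_codes(dosing: Sequence[DosingRule]) -> dict[str, frozenset[str]]:
    """Co-formulation drug codes with a recommended row somewhere."""
    out: dict[str, frozenset[str]] = {}
    for r in dosing:
        if r.formulation.is_fdc and r.status is DoseStatus.RECOMMENDED:
            out[r.formulation.drug_code] = frozenset(r.formulation.components)
    return out


def select_products(components: Iterable[str], age_years: float,
                    spec: ScenarioSpec, dosing: Sequence[DosingRule],
                    ) -> tuple[ProductSelection, ...]:
    """Deterministically map active components to purchasable products.

    With FDCs available, the largest co-formulation whose component set is a
    subset of the remaining components is taken first (exact component-set
    matching only); leftovers are covered by single products using the
    scenario's liquid/tablet schedule.
    """
    remaining = set(components)
    if not remaining:
        raise CostingError("no active components to select products for")
    single = _single_strategy(age_years, spec)
    picks: list[ProductSelection] = []
    if spec.fdc_available:
        fdcs = sorted(_fdc_codes(dosing).items(),
                      key=lambda kv: (-len(kv[1]), kv[0]))
        for code, comps in fdcs:
            if comps <= remaining:
                picks.append(ProductSelection(code, FormulationStrategy.TABLET_FIRST,
                                              comps))
                remaining -= comps
    for drug in sorted(remaining):
        if not any(r.formulation.drug_code == drug for r in dosing):
            raise CostingError(f"component {drug!r} has no product in the "
                               "dosing table")
        picks.append(ProductSelection(drug, single, frozenset({drug})))
    return tuple(picks)


def regimen_cost(regimen: Regimen, spec: ScenarioSpec,
                 probs: BandProbabilityRow,
                 dosing: Sequence[DosingRule],
                 prices: Sequence[PriceEntry],
                 days_per_month: float = DAYS_PER_MONTH) -> RegimenCostRow:
    """Monthly cost of a regimen at one age under one scenario."""
    comps = active_components(regimen, probs.age_years, spec)
    picks = select_products(comps, probs.age_years, spec, dosing)
    total = 0.0
    for pick in picks:
        cost: AgeCost = drug_cost_by_age(pick.drug_code, pick.strategy, probs,
                                         dosing, prices, days_per_month)
        total += cost.monthly_cost
    return RegimenCostRow(regimen, spec, probs.age_years, total, picks)


def regimen_cost_table(regimens: Sequence[Regimen],
                       scenarios: Sequence[ScenarioSpec],
                       prob_rows: Sequence[BandProbabilityRow],
                       dosing: Sequence[DosingRule],
                       prices: Sequence[PriceEntry],
                       days_per_month: float = DAYS_PER_MONTH,
                       ) -> list[RegimenCostRow]:
    """All regimen x scenario x age cost rows."""
    return [
        regimen_cost(reg, sc, probs, dosing, prices, days_per_month)
        for reg in regimens
        for sc in scenarios
        for probs in prob_rows
    ]
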