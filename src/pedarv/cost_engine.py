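"""Monthly ARV costs by weight band and by age.

The band-level arithmetic is a single product,

    monthly cost = average units per day * unit cost * 30.4 days/month,

kept unrounded internally; money is rounded only at render time.  Age-level
costs weight the band costs by the probability of being in each band at that
age.  Where a drug offers several formulations in the same band, one of two
deterministic strategies resolves the choice:

* ``liquid_first``  - syrup while recommended, then pediatric solid, then
  adult tablet (children stay on liquids as long as allowed);
* ``tablet_first``  - pediatric solid as soon as recommended, falling back
  to syrup in bands where the solid is not recommended (e.g. LPV/r tablets
  below 10 kg), then adult tablet.

Bands where a drug has no recommended formulation at all contribute zero
cost without renormalizing the remaining mass.  EFV carries an explicit
minimum-age overlay (not recommended below 3 years at any weight).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .growth import BandProbabilityRow
from .reference_data import (
    WEIGHT_BANDS,
    DoseStatus,
    DosingRule,
    Form,
    Formulation,
    PriceEntry,
    WeightBand,
)

__all__ = [
    "DAYS_PER_MONTH",
    "DRUG_MIN_AGE_YEARS",
    "CostingError",
    "NotRecommendedError",
    "FormulationStrategy",
    "BandCost",
    "AgeCost",
    "monthly_cost_by_band",
    "band_cost_table",
    "resolve_formulation",
    "drug_cost_by_age",
    "drug_cost_table",
    "dosing_index",
    "price_index",
]

#: Average days per month used to convert daily doses to monthly cost.
DAYS_PER_MONTH: float = 30.4

#: Age gates layered on top of the weight-band rules: a drug listed here has
#: no recommended formulation at any weight below the given age (years).
DRUG_MIN_AGE_YEARS: dict[str, float] = {"EFV": 3.0}


class CostingError(ValueError):
    """Raised when a cost is requested for an invalid combination."""


class NotRecommendedError(CostingError):
    """The drug has no recommended formulation for this band or age."""


class FormulationStrategy(str, enum.Enum):
    """Order in which formulation tiers are tried within a band."""

    LIQUID_FIRST = "liquid_first"
    TABLET_FIRST = "tablet_first"

    @property
    def tier_order(self) -> tuple[str, ...]:
        if self is FormulationStrategy.LIQUID_FIRST:
            return ("liquid", "pediatric", "adult")
        return ("pediatric", "liquid", "adult")


@dataclass(frozen=True)
class BandCost:
    """Monthly cost (USD) of one formulation in one weight band."""

    formulation: Formulation
    band: WeightBand
    monthly_cost: float
    monthly_cost_high: Optional[float] = None


@dataclass(frozen=True)
class AgeCost:
    """Probability-weighted monthly cost (USD) of one drug at one age."""

    drug_code: str
    strategy: FormulationStrategy
    age_years: float
    monthly_cost: float
    monthly_cost_high: Optional[float] = None


DosingIndex = Mapping[tuple[tuple[str, str], str], DosingRule]
PriceIndex = Mapping[tuple[str, str], PriceEntry]


def dosing_index(rules: Iterable[DosingRule]) -> dict[tuple[tuple[str, str], str], DosingRule]:
    """Index dosing rules by ((drug, strength), band label)."""
    return {(r.formulation.key, r.band.label): r for r in rules}


def price_index(prices: Iterable[PriceEntry]) -> dict[tuple[str, str], PriceEntry]:
    return {p.formulation.key: p for p in prices}


def monthly_cost_by_band(rule: DosingRule, price: PriceEntry,
                         days_per_month: float = DAYS_PER_MONTH) -> BandCost:
    """Monthly cost of one recommended dosing rule at a unit price."""
    if rule.status is not DoseStatus.RECOMMENDED:
        raise NotRecommendedError(
            f"{rule.formulation} is {rule.status.value} in {rule.band.label}; "
            "no cost defined"
        )
    if price.formulation.key != rule.formulation.key:
        raise CostingError(
            f"price for {price.formulation} does not match rule for "
            f"{rule.formulation}"
        )
    daily = rule.daily_units
    cost = daily * price.unit_cost * days_per_month
    high = (daily * price.unit_cost_high * days_per_month
            if price.unit_cost_high is not None else None)
    return BandCost(rule.formulation, rule.band, cost, high)


def band_cost_table(rules: Sequence[DosingRule],
                    prices: Sequence[PriceEntry],
                    days_per_month: float = DAYS_PER_MONTH) -> list[BandCost]:
    """Band costs for every recommended (formulation, band) pair."""
    pidx = price_index(prices)
    out = []
    for r in rules:
        if r.status is not DoseStatus.RECOMMENDED:
            continue
        price = pidx.get(r.formulation.key)
        if price is None:
            raise CostingError(f"no price for {r.formulation}")
        out.append(monthly_cost_by_band(r, price, days_per_month))
    return out


def _tier(form: Form) -> str:
    return form.tier


def resolve_formulation(drug_code: str, band: WeightBand,
                        strategy: FormulationStrategy,
                        dosing: Sequence[DosingRule]) -> DosingRule:
    """The unique dosing rule a strategy selects for a drug in a band.

    Raises :class:`NotRecommendedError` when no formulation of the drug is
    recommended in the band (e.g. EFV below 10 kg).
    """
    candidates = [r for r in dosing
                  if r.formulation.drug_code == drug_code
                  and r.band == band
                  and r.status is DoseStatus.RECOMMENDED]
    if not any(r.formulation.drug_code == drug_code for r in dosing):
        raise CostingError(f"drug {drug_code!r} absent from dosing table")
    if not candidates:
        raise NotRecommendedError(
            f"{drug_code} has no recommended formulation in {band.label}"
        )
    for tier in strategy.tier_order:
        in_tier = sorted((r for r in candidates if _tier(r.formulation.form) == tier),
                         key=lambda r: r.formulation.strength)
        if in_tier:
            return in_tier[0]
    raise NotRecommendedError(  # pragma: no cover - tiers are exhaustive
        f"{drug_code} has no resolvable formulation in {band.label}"
    )


def drug_cost_by_age(drug_code: str, strategy: FormulationStrategy,
                     probs: BandProbabilityRow,
                     dosing: Sequence[DosingRule],
                     prices: Sequence[PriceEntry],
                     days_per_month: float = DAYS_PER_MONTH,
                     min_age_years: Optional[Mapping[str, float]] = None,
                     ) -> AgeCost:
    """Probability-weighted monthly cost of one drug at one age.

    Band mass where the drug has no recommended formulation contributes zero
    (it is not renormalized away).  If no band with positive mass has a
    recommended formulation — or the drug's age gate excludes this age —
    a :class:`NotRecommendedError` is raised, mirroring the "NR" cells of an
    age-cost table.
    """
    gates = DRUG_MIN_AGE_YEARS if min_age_years is None else min_age_years
    gate = gates.get(drug_code)
    if gate is not None and probs.age_years < gate:
        raise NotRecommendedError(
            f"{drug_code} is not recommended below age {gate} "
            f"(requested {probs.age_years})"
        )
    pidx = price_index(prices)
    total = 0.0
    total_high = 0.0
    has_high = False
    covered_mass = 0.0
    for band, p in zip(WEIGHT_BANDS, probs.probs):
        if p == 0.0:
            continue
        try:
            rule = resolve_formulation(drug_code, band, strategy, dosing)
        except NotRecommendedError:
            continue
        price = pidx.get(rule.formulation.key)
        if price is None:
            raise CostingError(f"no price for {rule.formulation}")
        bc = monthly_cost_by_band(rule, price, days_per_month)
        covered_mass += p
        total += p * bc.monthly_cost
        if bc.monthly_cost_high is not None:
            has_high = True
            total_high += p * bc.monthly_cost_high
        else:
            total_high += p * bc.monthly_cost
    if covered_mass == 0.0:
        raise NotRecommendedError(
            f"{drug_code} has no recommended formulation in any occupied "
            f"weight band at age {probs.age_years}"
        )
    return AgeCost(drug_code, strategy, probs.age_years, total,
                   total_high if has_high else None)


def drug_cost_table(drug_strategies: Sequence[tuple[str, FormulationStrategy]],
                    prob_rows: Sequence[BandProbabilityRow],
                    dosing: Sequence[DosingRule],
                    prices: Sequence[PriceEntry],
                    days_per_month: float = DAYS_PER_MONTH,
                    ) -> dict[tuple[str, FormulationStrategy], list[Optional[AgeCost]]]:
    """Age-cost rows for several (drug, strategy) pairs; ``None`` marks NR ages."""
    out: dict[tuple[str, FormulationStrategy], list[Optional[AgeCost]]] = {}
    for drug, strategy in drug_strategies:
        row: list[Optional[AgeCost]] = []
        for probs in prob_rows:
            try:
                row.append(drug_cost_by_age(drug, strategy, probs,
                                            dosing, prices, days_per_month))
            except NotRecommendedError:
                row.append(None)
        out[(drug, strategy)] = row
    return out
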