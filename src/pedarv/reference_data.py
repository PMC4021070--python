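"""Controlled vocabularies and reference tables for pediatric ARV costing.

This module defines the seven WHO weight bands, drug formulations (including
dual/triple fixed-dose combinations), weight-band dosing rules and unit
prices, together with CSV loaders/writers for each.  All downstream costing
is driven by these tables; nothing here knows about ages or growth charts.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "WeightBand",
    "WEIGHT_BANDS",
    "BAND_BY_LABEL",
    "Form",
    "Formulation",
    "DoseStatus",
    "DosingRule",
    "PriceEntry",
    "ReferenceDataError",
    "load_dosing_table",
    "load_price_list",
    "write_dosing_table",
    "write_price_list",
    "validate_price_coverage",
    "packaged_path",
    "load_packaged_dosing",
    "load_packaged_prices",
]


class ReferenceDataError(ValueError):
    """Raised for malformed or inconsistent reference tables."""


@dataclass(frozen=True, order=True)
class WeightBand:
    """One WHO weight interval [lower_kg, upper_kg) in kilograms.

    The last band is open-ended (``upper_kg`` is ``math.inf``).
    """

    lower_kg: float
    upper_kg: float
    label: str = field(compare=False)

    def __post_init__(self) -> None:
        if not self.lower_kg < self.upper_kg:
            raise ReferenceDataError(
                f"band {self.label!r}: lower bound must be below upper bound"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: The canonical seven WHO dosing bands.  Bands are contiguous: each band's
#: integration upper limit is the next band's lower bound, so the printed
#: cut-point pairs (5.9, 6.0) etc. leave no gap.
WEIGHT_BANDS: tuple[WeightBand, ...] = (
    WeightBand(3.0, 6.0, "3-5.9 kg"),
    WeightBand(6.0, 10.0, "6-9.9 kg"),
    WeightBand(10.0, 14.0, "10-13.9 kg"),
    WeightBand(14.0, 20.0, "14-19.9 kg"),
    WeightBand(20.0, 25.0, "20-24.9 kg"),
    WeightBand(25.0, 35.0, "25-34.9 kg"),
    WeightBand(35.0, math.inf, "35+ kg"),
)

BAND_BY_LABEL: dict[str, WeightBand] = {b.label: b for b in WEIGHT_BANDS}


class Form(str, enum.Enum):
    """Physical formulation class, ordered by administration tier."""

    LIQUID = "liquid"
    PEDIATRIC_TABLET = "pediatric_tablet"
    ADULT_TABLET = "adult_tablet"
    CAPSULE = "capsule"

    @property
    def tier(self) -> str:
        """Resolution tier: liquid / pediatric solid / adult solid."""
        if self is Form.LIQUID:
            return "liquid"
        if self is Form.ADULT_TABLET:
            return "adult"
        return "pediatric"


@dataclass(frozen=True)
class Formulation:
    """A single product: drug (or co-formulation) at one strength."""

    drug_code: str
    strength: str
    form: Form
    components: frozenset[str]

    def __post_init__(self) -> None:
        if not self.components:
            raise ReferenceDataError("formulation needs at least one component")

    @property
    def is_fdc(self) -> bool:
        return len(self.components) > 1

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug_code, self.strength)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.drug_code} ({self.strength})"


class DoseStatus(str, enum.Enum):
    RECOMMENDED = "recommended"
    NOT_RECOMMENDED = "not_recommended"  # printed "NR"
    NOT_DOSED = "not_dosed"              # printed "-"


@dataclass(frozen=True)
class DosingRule:
    """Recommended dose of one formulation in one weight band.

    ``units_per_dose`` is in tablets/capsules/ml per administration and may be
    fractional (0.5 tab).  Asymmetric morning/evening rows ("1 tab am +
    0.5 tab pm") carry ``units_am``/``units_pm`` instead.
    """

    formulation: Formulation
    band: WeightBand
    units_per_dose: Optional[float] = None
    doses_per_day: Optional[int] = None
    units_am: Optional[float] = None
    units_pm: Optional[float] = None
    status: DoseStatus = DoseStatus.RECOMMENDED

    def __post_init__(self) -> None:
        if self.status is DoseStatus.RECOMMENDED:
            if self.units_am is not None or self.units_pm is not None:
                if self.units_am is None or self.units_pm is None:
                    raise ReferenceDataError(
                        f"{self.formulation} {self.band}: am/pm doses must "
                        "both be given"
                    )
                if self.units_am <= 0 or self.units_pm <= 0:
                    raise ReferenceDataError(
                        f"{self.formulation} {self.band}: non-positive dose"
                    )
            else:
                if self.units_per_dose is None or self.doses_per_day is None:
                    raise ReferenceDataError(
                        f"{self.formulation} {self.band}: recommended rule "
                        "needs units_per_dose and frequency"
                    )
                if self.units_per_dose <= 0:
                    raise ReferenceDataError(
                        f"{self.formulation} {self.band}: non-positive dose"
                    )

    @property
    def is_asymmetric(self) -> bool:
        return self.units_am is not None

    @property
    def daily_units(self) -> float:
        """Average units administered per day."""
        if self.status is not DoseStatus.RECOMMENDED:
            raise ReferenceDataError(
                f"{self.formulation} not recommended in {self.band.label}; "
                "no daily dose defined"
            )
        if self.is_asymmetric:
            return self.units_am + self.units_pm  # type: ignore[operator]
        return self.units_per_dose * self.doses_per_day  # type: ignore[operator]


@dataclass(frozen=True)
class PriceEntry:
    """Unit cost (2012 USD) per tablet/capsule/ml of one formulation.

    ``unit_cost_high`` is set for ranged prices; otherwise it equals the
    point price conceptually and is left ``None``.
    """

    formulation: Formulation
    unit_cost: float
    unit_cost_high: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.unit_cost > 0:
            raise ReferenceDataError(
                f"{self.formulation}: unit cost must be positive"
            )
        if self.unit_cost_high is not None and self.unit_cost_high < self.unit_cost:
            raise ReferenceDataError(
                f"{self.formulation}: high price below low price"
            )


_FREQ = {"qd": 1, "bid": 2}
_FREQ_INV = {1: "qd", 2: "bid"}


def _parse_formulation(drug: str, strength: str, form: str,
                       components: str) -> Formulation:
    try:
        f = Form(form)
    except ValueError as exc:
        raise ReferenceDataError(f"unknown form {form!r} for {drug}") from exc
    comps = frozenset(c.strip() for c in components.split(";") if c.strip()) \
        if components else frozenset({drug})
    return Formulation(drug_code=drug, strength=strength, form=f,
                       components=comps)


def load_dosing_table(path: str | Path) -> list[DosingRule]:
    """Load a weight-band dosing table from CSV.

    Expected columns: drug, strength, form, components, band, units_per_dose,
    units_am, units_pm, frequency, status.  Band labels must match the seven
    canonical labels exactly (no fuzzy matching: silent band misassignment is
    the worst failure mode here).  Every (formulation, band) pair may appear
    at most once and each formulation must account for all 7 bands.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"drug", "strength", "band", "status"}
    if missing := required - set(df.columns):
        raise ReferenceDataError(f"dosing table missing columns: {sorted(missing)}")
    rules: list[DosingRule] = []
    seen: set[tuple[tuple[str, str], str]] = set()
    for row in df.itertuples(index=False):
        band_label = row.band.strip()
        if band_label not in BAND_BY_LABEL:
            raise ReferenceDataError(f"unknown band label {band_label!r}")
        formulation = _parse_formulation(
            row.drug.strip(), row.strength.strip(),
            getattr(row, "form", "").strip() or "adult_tablet",
            getattr(row, "components", "").strip(),
        )
        key = (formulation.key, band_label)
        if key in seen:
            raise ReferenceDataError(
                f"duplicate dosing row for {formulation} in {band_label}"
            )
        seen.add(key)
        status = DoseStatus(row.status.strip())
        band = BAND_BY_LABEL[band_label]
        if status is not DoseStatus.RECOMMENDED:
            rules.append(DosingRule(formulation, band, status=status))
            continue
        units_am = float(row.units_am) if row.units_am else None
        units_pm = float(row.units_pm) if row.units_pm else None
        if units_am is not None or units_pm is not None:
            rules.append(DosingRule(formulation, band,
                                    units_am=units_am, units_pm=units_pm,
                                    doses_per_day=2, status=status))
        else:
            units = float(row.units_per_dose) if row.units_per_dose else None
            if units is not None and units < 0:
                raise ReferenceDataError(
                    f"negative dose for {formulation} in {band_label}"
                )
            freq = row.frequency.strip()
            if freq not in _FREQ:
                raise ReferenceDataError(
                    f"bad frequency {freq!r} for {formulation} in {band_label}"
                )
            rules.append(DosingRule(formulation, band,
                                    units_per_dose=units,
                                    doses_per_day=_FREQ[freq], status=status))
    # every formulation must cover all 7 bands
    by_form: dict[tuple[str, str], set[str]] = {}
    for r in rules:
        by_form.setdefault(r.formulation.key, set()).add(r.band.label)
    for fkey, bands in by_form.items():
        if bands != set(BAND_BY_LABEL):
            absent = sorted(set(BAND_BY_LABEL) - bands)
            raise ReferenceDataError(
                f"formulation {fkey} missing bands {absent}"
            )
    return rules


def write_dosing_table(rules: Sequence[DosingRule], path: str | Path) -> None:
    """Write dosing rules back to the CSV layout read by ``load_dosing_table``."""
    recs = []
    for r in rules:
        rec = {"drug": r.formulation.drug_code,
               "strength": r.formulation.strength,
               "form": r.formulation.form.value,
               "components": ";".join(sorted(r.formulation.components)),
               "band": r.band.label,
               "units_per_dose": "", "units_am": "", "units_pm": "",
               "frequency": "", "status": r.status.value}
        if r.status is DoseStatus.RECOMMENDED:
            if r.is_asymmetric:
                rec["units_am"] = _fmt_num(r.units_am)
                rec["units_pm"] = _fmt_num(r.units_pm)
                rec["frequency"] = "bid"
            else:
                rec["units_per_dose"] = _fmt_num(r.units_per_dose)
                rec["frequency"] = _FREQ_INV[r.doses_per_day]
        recs.append(rec)
    pd.DataFrame(recs).to_csv(path, index=False)


def _fmt_num(x: float | None) -> str:
    if x is None:
        return ""
    return str(int(x)) if float(x) == int(x) else str(float(x))


def load_price_list(path: str | Path,
                    formulations: Optional[Iterable[Formulation]] = None,
                    ) -> list[PriceEntry]:
    """Load unit prices from CSV (columns drug, strength, unit_cost,
    unit_cost_high).

    When ``formulations`` is given, price entries are attached to those
    formulation objects (matched on drug/strength); otherwise minimal
    formulation stubs are created.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    if df.empty:
        raise ReferenceDataError(f"price list {path} is empty")
    if missing := {"drug", "strength", "unit_cost"} - set(df.columns):
        raise ReferenceDataError(f"price list missing columns: {sorted(missing)}")
    lookup = {f.key: f for f in formulations} if formulations else {}
    entries: list[PriceEntry] = []
    for row in df.itertuples(index=False):
        key = (row.drug.strip(), row.strength.strip())
        formulation = lookup.get(key) or _parse_formulation(
            key[0], key[1], "adult_tablet", "")
        try:
            cost = float(row.unit_cost)
        except ValueError as exc:
            raise ReferenceDataError(
                f"non-numeric price for {key}: {row.unit_cost!r}") from exc
        high_raw = getattr(row, "unit_cost_high", "")
        high = float(high_raw) if str(high_raw).strip() else None
        entries.append(PriceEntry(formulation, cost, high))
    return entries


def write_price_list(entries: Sequence[PriceEntry], path: str | Path) -> None:
    recs = [{"drug": e.formulation.drug_code,
             "strength": e.formulation.strength,
             "unit_cost": e.unit_cost,
             "unit_cost_high": "" if e.unit_cost_high is None else e.unit_cost_high}
            for e in entries]
    pd.DataFrame(recs).to_csv(path, index=False)


def validate_price_coverage(rules: Sequence[DosingRule],
                            prices: Sequence[PriceEntry]) -> list[str]:
    """Return a gap report: formulations recommended somewhere but unpriced.

    An empty list means every recommended formulation has a price.
    """
    priced = {e.formulation.key for e in prices}
    gaps = []
    seen: set[tuple[str, str]] = set()
    for r in rules:
        if r.status is DoseStatus.RECOMMENDED and r.formulation.key not in priced:
            if r.formulation.key not in seen:
                seen.add(r.formulation.key)
                gaps.append(f"no price for {r.formulation}")
    return gaps


# -- packaged fixtures -------------------------------------------------------

def packaged_path(name: str) -> Path:
    """Path of a packaged reference CSV (e.g. ``dosing_who_2010_2013.csv``)."""
    return Path(str(resources.files("pedarv").joinpath("data", name)))


def load_packaged_dosing() -> list[DosingRule]:
    return load_dosing_table(packaged_path("dosing_who_2010_2013.csv"))


def load_packaged_prices(rules: Optional[Sequence[DosingRule]] = None,
                         ) -> list[PriceEntry]:
    forms = {r.formulation for r in rules} if rules else None
    return load_price_list(packaged_path("prices_chai_2012.csv"), forms)
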