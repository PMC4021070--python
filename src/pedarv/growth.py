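"""Weight-for-age growth model: LMS references to weight-band probabilities.

Growth references (WHO Child Growth Standards below 5 years, CDC Growth
Charts above) tabulate three parameters per age and sex: the Box-Cox power
``L``, the median weight ``M`` (kg) and the generalized coefficient of
variation ``S``.  For a child of weight ``w`` the reference z-score is

    z = ((w/M)**L - 1) / (L*S)     for L != 0
    z = ln(w/M) / S                for L == 0

HIV-infected children are on average lighter than the general population, so
the reference distribution is relocated in z-space: a child at reference
z-score ``Z`` (default -1.5) becomes the new median, and the spread may be
rescaled by a factor ``k`` on the coefficient of variation,

    z_adj = (z - Z) / k,    z_adj ~ N(0, 1).

The probability of lying in a weight band is then the difference of standard
normal CDFs at the band bounds' adjusted z-scores, renormalized over the
seven bands (mass below 3 kg is discarded, matching probability tables that
sum to one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .reference_data import WEIGHT_BANDS, WeightBand

__all__ = [
    "LMSRecord",
    "PopulationAdjustment",
    "BandProbabilityRow",
    "GrowthModelError",
    "lms_zscore",
    "lms_weight_from_zscore",
    "adjusted_zscore",
    "interpolate_lms",
    "band_probabilities",
    "average_sexes",
    "band_probability_table",
    "generate_synthetic_lms",
    "load_lms_table",
    "write_lms_table",
    "load_band_probability_table",
    "write_band_probability_table",
    "PAPER_AGE_GRID",
]

#: Ages (years) at which band probabilities are tabulated: 6 months, then
#: whole years through 13.
PAPER_AGE_GRID: tuple[float, ...] = (0.5,) + tuple(float(a) for a in range(1, 14))

_SEXES = ("male", "female")


class GrowthModelError(ValueError):
    """Raised for invalid growth-model inputs (bad ages, degenerate mass...)."""


@dataclass(frozen=True)
class LMSRecord:
    """Box-Cox growth-reference triple at one age and sex."""

    age_months: float
    sex: str
    L: float
    M: float
    S: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise GrowthModelError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if not self.M > 0:
            raise GrowthModelError("median weight M must be positive")
        if not self.S > 0:
            raise GrowthModelError("coefficient of variation S must be positive")


@dataclass(frozen=True)
class PopulationAdjustment:
    """Relocation/rescaling of the reference weight distribution in z-space.

    ``z_shift`` is the reference z-score that becomes the adjusted median
    (default -1.5 for HIV-infected children); ``cv_multiplier`` scales the
    coefficient of variation (1 = same spread as the general population).
    """

    z_shift: float = -1.5
    cv_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not self.cv_multiplier > 0:
            raise GrowthModelError("cv_multiplier must be positive")


#: The unadjusted general-population reference.
IDENTITY_ADJUSTMENT = PopulationAdjustment(z_shift=0.0, cv_multiplier=1.0)


@dataclass(frozen=True)
class BandProbabilityRow:
    """Probability mass in each of the seven WHO weight bands at one age."""

    age_years: float
    probs: tuple[float, ...]
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.probs) != len(WEIGHT_BANDS):
            raise GrowthModelError("need one probability per weight band")
        if any(p < -1e-12 or p > 1 + 1e-12 for p in self.probs):
            raise GrowthModelError("probabilities must lie in [0, 1]")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise GrowthModelError("band probabilities must sum to 1")

    def prob(self, band: WeightBand) -> float:
        return self.probs[WEIGHT_BANDS.index(band)]

    def as_dict(self) -> dict[str, float]:
        return {b.label: p for b, p in zip(WEIGHT_BANDS, self.probs)}


def lms_zscore(weight_kg: float, rec: LMSRecord) -> float:
    """Reference z-score of ``weight_kg`` under an LMS triple."""
    if not weight_kg > 0:
        raise GrowthModelError("weight must be positive")
    # |L| below ~1e-7 is numerically the log branch (the Box-Cox limit);
    # evaluating the power form there loses all precision to cancellation.
    if abs(rec.L) < 1e-7:
        return math.log(weight_kg / rec.M) / rec.S
    return ((weight_kg / rec.M) ** rec.L - 1.0) / (rec.L * rec.S)


def lms_weight_from_zscore(z: float, rec: LMSRecord) -> float:
    """Inverse of :func:`lms_zscore` (the weight at reference z-score ``z``)."""
    if abs(rec.L) < 1e-7:
        return rec.M * math.exp(rec.S * z)
    base = 1.0 + rec.L * rec.S * z
    if base <= 0:
        raise GrowthModelError(f"z={z} outside the Box-Cox support for this record")
    return rec.M * base ** (1.0 / rec.L)


def adjusted_zscore(weight_kg: float, rec: LMSRecord,
                    adj: PopulationAdjustment) -> float:
    """z-score of ``weight_kg`` in the shifted/rescaled population."""
    return (lms_zscore(weight_kg, rec) - adj.z_shift) / adj.cv_multiplier


def interpolate_lms(age_months: float, sex: str,
                    lms_table: Iterable[LMSRecord]) -> LMSRecord:
    """LMS triple at an arbitrary age, linear in (L, M, S) between the
    bracketing tabulated ages for the requested sex."""
    recs = sorted((r for r in lms_table if r.sex == sex),
                  key=lambda r: r.age_months)
    if not recs:
        raise GrowthModelError(f"no LMS records for sex {sex!r}")
    ages = [r.age_months for r in recs]
    if not ages[0] <= age_months <= ages[-1]:
        raise GrowthModelError(
            f"age {age_months} months outside LMS coverage "
            f"[{ages[0]}, {ages[-1]}]"
        )
    hi = np.searchsorted(ages, age_months)
    if hi < len(ages) and ages[hi] == age_months:
        return recs[hi]
    lo, hi = recs[hi - 1], recs[hi]
    t = (age_months - lo.age_months) / (hi.age_months - lo.age_months)
    return LMSRecord(
        age_months=age_months, sex=sex,
        L=lo.L + t * (hi.L - lo.L),
        M=lo.M + t * (hi.M - lo.M),
        S=lo.S + t * (hi.S - lo.S),
        source=lo.source if lo.source == hi.source else f"{lo.source}|{hi.source}",
    )


def band_probabilities(age_years: float, sex: str,
                       lms_table: Iterable[LMSRecord],
                       adj: PopulationAdjustment = PopulationAdjustment(),
                       ) -> BandProbabilityRow:
    """Probability of being in each WHO weight band at ``age_years``.

    Each band contributes Phi(z_adj(upper)) - Phi(z_adj(lower)) with the
    next band's lower bound as the upper integration limit (restoring
    contiguity across the printed 5.9/6.0-style cut-point pairs); the open
    35+ band contributes 1 - Phi(z_adj(35)).  The seven masses are then
    renormalized so the row sums to one; if essentially no mass falls inside
    the bands this is an error rather than a silent zero row.
    """
    rec = interpolate_lms(age_years * 12.0, sex, lms_table)
    bounds = [b.lower_kg for b in WEIGHT_BANDS]
    cdf_at = [norm.cdf(adjusted_zscore(w, rec, adj)) for w in bounds]
    masses = [cdf_at[i + 1] - cdf_at[i] for i in range(len(bounds) - 1)]
    masses.append(1.0 - cdf_at[-1])
    total = sum(masses)
    if total < 1e-12:
        raise GrowthModelError(
            f"no probability mass in the weight bands at age {age_years} "
            f"(adjustment {adj})"
        )
    probs = tuple(max(m, 0.0) / total for m in masses)
    # guard against renormalization drift
    s = sum(probs)
    probs = tuple(p / s for p in probs)
    return BandProbabilityRow(age_years=age_years, probs=probs, sex=sex)


def average_sexes(male: BandProbabilityRow,
                  female: BandProbabilityRow) -> BandProbabilityRow:
    """Equal-weight average of the male and female band-probability rows."""
    if male.age_years != female.age_years:
        raise GrowthModelError(
            f"age mismatch: {male.age_years} vs {female.age_years}"
        )
    probs = tuple((m + f) / 2.0 for m, f in zip(male.probs, female.probs))
    return BandProbabilityRow(age_years=male.age_years, probs=probs)


def band_probability_table(lms_table: Iterable[LMSRecord],
                           adj: PopulationAdjustment = PopulationAdjustment(),
                           ages: Sequence[float] = PAPER_AGE_GRID,
                           ) -> list[BandProbabilityRow]:
    """Sex-averaged band probabilities over an age grid.

    Charts carrying only one sex (e.g. synthetic test charts) are used
    as-is; with both sexes present the rows are averaged equally.
    """
    lms_list = list(lms_table)
    sexes = sorted({r.sex for r in lms_list})
    rows = []
    for age in ages:
        per_sex = [band_probabilities(age, s, lms_list, adj) for s in sexes]
        if len(per_sex) == 1:
            rows.append(BandProbabilityRow(age, per_sex[0].probs))
        else:
            rows.append(average_sexes(per_sex[0], per_sex[1]))
    return rows


def generate_synthetic_lms(age_grid: Sequence[float] = PAPER_AGE_GRID,
                           sex: str = "male",
                           median_curve: Callable[[float], float] | tuple[float, float] = (3.0, 40.0),
                           cv: float = 0.12,
                           L_value: float = 1.0,
                           seed: int = 0,
                           jitter: float = 0.02) -> list[LMSRecord]:
    """Synthetic LMS chart for tests: a stand-in for WHO/CDC growth tables.

    ``median_curve`` is either a callable age_years -> median kg, or a
    (start, end) pair describing a linear median over the age grid.  The
    median must be strictly increasing with age.  ``seed`` drives a small
    deterministic log-normal jitter on S (set ``jitter=0`` for an exactly
    constant coefficient of variation).
    """
    if not cv > 0:
        raise GrowthModelError("cv must be positive")
    if sex not in _SEXES:
        raise GrowthModelError(f"sex must be one of {_SEXES}")
    ages = list(age_grid)
    if callable(median_curve):
        medians = [float(median_curve(a)) for a in ages]
    else:
        start, end = median_curve
        lo, hi = min(ages), max(ages)
        span = hi - lo or 1.0
        medians = [start + (end - start) * (a - lo) / span for a in ages]
    if any(b <= a for a, b in zip(medians, medians[1:])):
        raise GrowthModelError("median curve must be strictly increasing in age")
    rng = np.random.default_rng(seed)
    s_vals = cv * np.exp(jitter * rng.standard_normal(len(ages)))
    return [
        LMSRecord(age_months=a * 12.0, sex=sex, L=L_value, M=m,
                  S=float(s), source="synthetic")
        for a, m, s in zip(ages, medians, s_vals)
    ]


# -- CSV interfaces ----------------------------------------------------------

def load_lms_table(path: str | Path) -> list[LMSRecord]:
    """Load an LMS chart CSV (columns source, sex, age_months, L, M, S)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if missing := {"sex", "age_months", "L", "M", "S"} - set(df.columns):
        raise GrowthModelError(f"LMS table missing columns: {sorted(missing)}")
    return [
        LMSRecord(age_months=float(r.age_months), sex=str(r.sex),
                  L=float(r.L), M=float(r.M), S=float(r.S),
                  source=str(getattr(r, "source", "")))
        for r in df.itertuples(index=False)
    ]


def write_lms_table(records: Sequence[LMSRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"source": r.source, "sex": r.sex, "age_months": r.age_months,
          "L": r.L, "M": r.M, "S": r.S} for r in records]
    ).to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def load_band_probability_table(path: str | Path) -> list[BandProbabilityRow]:
    """Load a band-probability table CSV (age_years + one column per band).

    Rows are renormalized to absorb 3-decimal display rounding.
    """
    df = pd.read_csv(path)
    labels = [b.label for b in WEIGHT_BANDS]
    if missing := set(labels + ["age_years"]) - set(df.columns):
        raise GrowthModelError(
            f"band-probability table missing columns: {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        raw = [float(r[lbl]) for lbl in labels]
        total = sum(raw)
        if total <= 0:
            raise GrowthModelError(
                f"band-probability row at age {r['age_years']} has no mass")
        rows.append(BandProbabilityRow(
            age_years=float(r["age_years"]),
            probs=tuple(x / total for x in raw)))
    return rows


def write_band_probability_table(rows: Sequence[BandProbabilityRow],
                                 path: str | Path) -> None:
    pd.DataFrame(
        [{"age_years": r.age_years, **r.as_dict()} for r in rows]
    ).to_csv(path, index=False, float_format="%.6f")
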