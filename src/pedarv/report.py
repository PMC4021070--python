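"""Rendering of the pipeline's table shapes and the external-price comparison.

Money is kept unrounded throughout the computation and rounded half-up to
two decimals only here, at render time (commercial rounding reproduces the
conventional presentation of values like $34.66 from 34.656).  Every render
is deterministic: fixed column orders, fixed row orders, plain CSV.
"""

from __future__ import annotations

import hashlib
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .cost_engine import AgeCost, BandCost, FormulationStrategy
from .growth import BandProbabilityRow
from .reference_data import (
    WEIGHT_BANDS,
    DoseStatus,
    DosingRule,
    packaged_path,
)
from .regimen import RegimenCostRow

__all__ = [
    "round_half_up",
    "money",
    "band_cost_frame",
    "band_probability_frame",
    "age_cost_frame",
    "regimen_cost_frame",
    "load_gprm_reference",
    "compare_to_reference",
    "write_csv",
    "log_run_provenance",
]

logger = logging.getLogger(__name__)


def round_half_up(x: float, places: int = 2) -> float:
    """Commercial (half-up) rounding, e.g. 34.656 -> 34.66, 2.435 -> 2.44."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def money(x: Optional[float]) -> str:
    """Two-decimal money string; empty for missing."""
    if x is None:
        return ""
    return f"{round_half_up(x):.2f}"


def _money_cell(low: Optional[float], high: Optional[float]) -> str:
    if low is None:
        return ""
    if high is None:
        return money(low)
    return f"{money(low)}-{money(high)}"


def band_cost_frame(costs: Sequence[BandCost],
                    dosing: Optional[Sequence[DosingRule]] = None) -> pd.DataFrame:
    """Formulation x band monthly-cost table (the by-weight cost layout).

    With ``dosing`` given, not-recommended cells render as ``NR`` and
    not-dosed cells as empty; formulation row order follows the dosing table.
    """
    by_key: dict[tuple[tuple[str, str], str], BandCost] = {
        (c.formulation.key, c.band.label): c for c in costs
    }
    if dosing is not None:
        order = list(dict.fromkeys(r.formulation for r in dosing))
        status = {(r.formulation.key, r.band.label): r.status for r in dosing}
    else:
        order = list(dict.fromkeys(c.formulation for c in costs))
        status = {}
    rows = []
    for f in order:
        row: dict[str, str] = {"drug": f.drug_code, "strength": f.strength}
        for band in WEIGHT_BANDS:
            cell = by_key.get((f.key, band.label))
            if cell is not None:
                row[band.label] = _money_cell(cell.monthly_cost,
                                              cell.monthly_cost_high)
            elif status.get((f.key, band.label)) is DoseStatus.NOT_RECOMMENDED:
                row[band.label] = "NR"
            else:
                row[band.label] = ""
        rows.append(row)
    cols = ["drug", "strength"] + [b.label for b in WEIGHT_BANDS]
    return pd.DataFrame(rows, columns=cols)


def band_probability_frame(rows: Sequence[BandProbabilityRow]) -> pd.DataFrame:
    """Age x band probability table, probabilities at 3 decimals."""
    recs = [{"age_years": r.age_years,
             **{b.label: f"{p:.3f}" for b, p in zip(WEIGHT_BANDS, r.probs)}}
            for r in rows]
    return pd.DataFrame(recs, columns=["age_years"] + [b.label for b in WEIGHT_BANDS])


def age_cost_frame(table: Mapping[tuple[str, FormulationStrategy], Sequence[Optional[AgeCost]]],
                   ages: Sequence[float]) -> pd.DataFrame:
    """Drug/strategy x age monthly-cost table; NR cells render as ``NR``."""
    rows = []
    for (drug, strategy), row in table.items():
        rec: dict[str, str] = {"drug": drug, "strategy": strategy.value}
        for age, cost in zip(ages, row):
            rec[str(age)] = "NR" if cost is None else money(cost.monthly_cost)
        rows.append(rec)
    return pd.DataFrame(rows, columns=["drug", "strategy"] + [str(a) for a in ages])


def regimen_cost_frame(rows: Sequence[RegimenCostRow]) -> pd.DataFrame:
    """Regimen x scenario x age monthly-cost table (one row per regimen and
    scenario, one column per age)."""
    ages = sorted({r.age_years for r in rows})
    keyed: dict[tuple[str, int], dict[float, float]] = {}
    for r in rows:
        keyed.setdefault((r.regimen.label, r.scenario.scenario_id), {})[
            r.age_years] = r.monthly_cost
    recs = []
    for (label, sid), by_age in keyed.items():
        rec = {"regimen": label, "scenario": sid}
        for a in ages:
            rec[str(a)] = money(by_age.get(a))
        recs.append(rec)
    return pd.DataFrame(recs, columns=["regimen", "scenario"] + [str(a) for a in ages])


# -- comparison against an external transaction-price reference --------------

def load_gprm_reference(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Load a reference monthly-price table (columns drug, strength, scope,
    gprm_monthly_cost; 'N/A' cells allowed).  Defaults to the packaged
    transaction-price reference."""
    if path is None:
        path = packaged_path("gprm_reference.csv")
    return pd.read_csv(path, dtype=str).fillna("N/A")


def compare_to_reference(derived: Sequence[BandCost],
                         reference: pd.DataFrame,
                         pediatric_bands: tuple[str, str] = ("6-9.9 kg", "10-13.9 kg"),
                         adult_band: str = "35+ kg") -> pd.DataFrame:
    """Side-by-side derived vs reference monthly costs with differences.

    Pediatric reference prices (quoted for a ~10 kg child) are compared to
    the derived costs in the two bands around 10 kg; adult prices to the
    35+ kg band.  Reference rows with no derived counterpart are flagged
    ``no derived cost`` rather than dropped; 'N/A' reference cells are
    carried through with empty difference columns.
    """
    by_key: dict[tuple[tuple[str, str], str], BandCost] = {
        (c.formulation.key, c.band.label): c for c in derived
    }
    if reference.empty:
        logger.warning("reference price table is empty; emitting all-N/A table")
    recs = []
    for row in reference.itertuples(index=False):
        key = (row.drug, row.strength)
        scope = row.scope
        bands = list(pediatric_bands) if scope == "pediatric" else [adult_band]
        derived_cells = [by_key.get((key, b)) for b in bands]
        derived_vals = [c.monthly_cost for c in derived_cells if c is not None]
        ref_raw = str(row.gprm_monthly_cost)
        ref_val = None if ref_raw in ("", "N/A") else float(ref_raw)
        rec = {
            "drug": row.drug, "strength": row.strength, "scope": scope,
            "derived_low": money(min(derived_vals)) if derived_vals else "",
            "derived_high": money(max(derived_vals)) if derived_vals else "",
            "reference": money(ref_val) if ref_val is not None else "N/A",
            "note": "",
        }
        if not derived_vals:
            rec["note"] = "no derived cost"
            rec["abs_diff_low"] = rec["abs_diff_high"] = ""
            rec["ratio_low"] = rec["ratio_high"] = ""
        elif ref_val is None:
            rec["abs_diff_low"] = rec["abs_diff_high"] = ""
            rec["ratio_low"] = rec["ratio_high"] = ""
        else:
            lo, hi = min(derived_vals), max(derived_vals)
            rec["abs_diff_low"] = money(lo - ref_val)
            rec["abs_diff_high"] = money(hi - ref_val)
            rec["ratio_low"] = f"{lo / ref_val:.2f}"
            rec["ratio_high"] = f"{hi / ref_val:.2f}"
        recs.append(rec)
    cols = ["drug", "strength", "scope", "derived_low", "derived_high",
            "reference", "abs_diff_low", "abs_diff_high",
            "ratio_low", "ratio_high", "note"]
    return pd.DataFrame(recs, columns=cols)


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV render (fixed column order, no index)."""
    frame.to_csv(path, index=False)


def log_run_provenance(inputs: Mapping[str, str | Path],
                       parameters: Mapping[str, object]) -> None:
    """Log input-file hashes and run parameters for reproducibility."""
    for name, path in inputs.items():
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()[:16] \
            if p.exists() else "missing"
        logger.info("input %s: %s sha256:%s", name, p, digest)
    for name, value in parameters.items():
        logger.info("parameter %s = %r", name, value)
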