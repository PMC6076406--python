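"""Per-capita national nutrient availability from item-level supply records.

The core accounting identity: the availability of nutrient *i* in country *c*
and year *t* is the sum, over all food items *j*, of the item's gross
per-capita supply, reduced by its refuse factor and multiplied by its nutrient
density per 100 g edible portion.  Energy is then computed from the aggregated
protein, carbohydrate-by-difference, fat, and alcohol masses via the Atwater
factors, so the four macronutrient energy shares close to 100% exactly.

Availability is an upper bound on consumption — it is what reaches the
household, before retail and household waste — never an intake estimate.

A location-year with no supply rows is *missing* (to be gap-filled
downstream), not zero; a present row with zero quantity is a true zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import (
    ATWATER_KCAL_PER_G,
    CompositionRecord,
    carbohydrate_by_difference_table,
    validate_matching,
)
from .errors import DomainError, LookupError_, SchemaError, UndefinedStatisticError, UnitMismatchError

DAYS_PER_YEAR = 365.25  # averages leap years

#: density-column suffix -> per-capita unit of the aggregated nutrient
UNIT_BY_SUFFIX = {"_g": "g/person/day", "_mg": "mg/person/day", "_ug": "ug/person/day"}

#: macronutrient -> (mass column, kcal/g) used for the energy decomposition
MACRO_ENERGY = {
    "protein": ("protein_g", ATWATER_KCAL_PER_G["protein"]),
    "carbohydrate": ("carbohydrate_g", ATWATER_KCAL_PER_G["carbohydrate"]),
    "fat": ("fat_g", ATWATER_KCAL_PER_G["fat"]),
    "mufa": ("mufa_g", ATWATER_KCAL_PER_G["fat"]),
    "pufa": ("pufa_g", ATWATER_KCAL_PER_G["fat"]),
    "sfa": ("sfa_g", ATWATER_KCAL_PER_G["fat"]),
    "alcohol": ("alcohol_g", ATWATER_KCAL_PER_G["alcohol"]),
}

#: the four macronutrients whose energies partition total Atwater energy
PRIMARY_MACROS = ("carbohydrate", "protein", "fat", "alcohol")

PANEL_COLUMNS = ["location_id", "year", "nutrient_id", "value", "unit", "lower", "upper", "observed"]


@dataclass(frozen=True)
class SupplyRecord:
    """Gross per-capita availability of one food item in one country-year."""

    location_id: str
    year: int
    item_id: str
    gross_supply_g_per_person_day: float


def nutrient_unit(nutrient_id: str) -> str:
    """Unit string for a panel nutrient id (mass suffix or kcal)."""
    if nutrient_id == "energy_kcal" or nutrient_id.endswith("_kcal"):
        return "kcal/person/day"
    for suffix, unit in UNIT_BY_SUFFIX.items():
        if nutrient_id.endswith(suffix):
            return unit
    raise SchemaError(f"cannot infer unit for nutrient {nutrient_id!r}")


def per_capita_supply(raw_tonnes_per_year, population):
    """Convert a national quantity (tonnes/year) to g/person/day."""
    tonnes = np.asarray(raw_tonnes_per_year, dtype=float)
    pop = np.asarray(population, dtype=float)
    if np.any(pop <= 0):
        raise DomainError("population must be positive")
    out = tonnes * 1e6 / pop / DAYS_PER_YEAR
    return float(out) if out.ndim == 0 else out


def item_nutrient_contribution(
    supply: SupplyRecord, record: CompositionRecord, nutrient_id: str
) -> float:
    """Per-capita contribution of one item to one nutrient.

    ``gross * (1 - refuse) * density_per_100g / 100`` in the nutrient's unit.
    """
    record.validate()
    if supply.item_id != record.item_id:
        raise LookupError_(
            f"supply item {supply.item_id!r} does not match composition record "
            f"{record.item_id!r}"
        )
    if hasattr(record, nutrient_id):
        density = getattr(record, nutrient_id)
    elif nutrient_id in record.micronutrients:
        density = record.micronutrients[nutrient_id][0]
    else:
        raise LookupError_(f"nutrient {nutrient_id!r} not in composition record")
    edible = supply.gross_supply_g_per_person_day * (1.0 - record.refuse_fraction)
    return edible * density / 100.0


def _density_columns(composition: pd.DataFrame) -> list[str]:
    skip = {"item_id", "refuse_fraction", "energy_kcal"}
    cols = []
    for col in composition.columns:
        if col in skip:
            continue
        if any(col.endswith(suffix) for suffix in UNIT_BY_SUFFIX):
            cols.append(col)
    return cols


def aggregate_availability(
    supply: pd.DataFrame,
    composition: pd.DataFrame,
    match: pd.DataFrame,
    allow_unmatched=None,
) -> pd.DataFrame:
    """Sum item contributions into a nutrient x location x year panel.

    Parameters
    ----------
    supply
        Long table with ``location_id, year, item_id`` and either
        ``gross_supply_g_per_person_day`` or ``raw_tonnes_per_year`` +
        ``population`` (converted internally).
    composition
        One row per item: ``item_id, refuse_fraction, energy_kcal`` and
        nutrient-density columns per 100 g edible (``protein_g, fat_g, ...,
        iron_mg, vita_rae_ug``).  Digestible carbohydrate is derived by
        difference from the stored energy, never read from a column.
    match
        ``supply_item_id -> composition_item_id`` mapping; validated before
        any arithmetic, and unmatched items abort unless allow-listed.

    Returns
    -------
    Long panel ``location_id, year, nutrient_id, value, unit, lower, upper,
    observed`` covering every nutrient density column, the macronutrient
    energies (``*_kcal``), and total ``energy_kcal`` computed via Atwater
    from the aggregated macronutrient masses.
    """
    report = validate_matching(
        match, supply["item_id"].unique(), composition, allow_unmatched=allow_unmatched
    )
    if not report.ok:
        raise LookupError_(f"matching validation failed: {report.summary()}")

    supply = supply.copy()
    if "gross_supply_g_per_person_day" not in supply.columns:
        if {"raw_tonnes_per_year", "population"} <= set(supply.columns):
            supply["gross_supply_g_per_person_day"] = per_capita_supply(
                supply["raw_tonnes_per_year"].to_numpy(), supply["population"].to_numpy()
            )
        else:
            raise SchemaError(
                "supply table needs gross_supply_g_per_person_day or "
                "raw_tonnes_per_year + population"
            )
    if (supply["gross_supply_g_per_person_day"] < 0).any():
        raise DomainError("negative supply quantity")

    comp = composition.copy()
    comp["carbohydrate_g"] = carbohydrate_by_difference_table(comp)
    density_cols = _density_columns(comp)

    merged = supply.merge(
        match[["supply_item_id", "composition_item_id"]],
        left_on="item_id",
        right_on="supply_item_id",
        how="left",
    ).merge(
        comp[["item_id", "refuse_fraction"] + density_cols],
        left_on="composition_item_id",
        right_on="item_id",
        how="left",
        suffixes=("", "_comp"),
    )
    if merged["refuse_fraction"].isna().any():
        bad = merged.loc[merged["refuse_fraction"].isna(), "item_id"].unique().tolist()
        raise LookupError_(f"items without composition data: {bad[:10]}")

    edible = merged["gross_supply_g_per_person_day"].to_numpy() * (
        1.0 - merged["refuse_fraction"].to_numpy()
    )
    contrib = merged[density_cols].to_numpy(dtype=float) * edible[:, None] / 100.0
    per_cell = (
        pd.DataFrame(contrib, columns=density_cols)
        .assign(location_id=merged["location_id"].to_numpy(), year=merged["year"].to_numpy())
        .groupby(["location_id", "year"], as_index=False, sort=True)[density_cols]
        .sum()
    )

    # Energy decomposition from the aggregated macronutrient masses.
    for macro, (mass_col, kcal_per_g) in MACRO_ENERGY.items():
        if mass_col in per_cell.columns:
            per_cell[f"{macro}_kcal"] = per_cell[mass_col] * kcal_per_g
    energy_parts = [f"{m}_kcal" for m in PRIMARY_MACROS if f"{m}_kcal" in per_cell.columns]
    per_cell["energy_kcal"] = per_cell[energy_parts].sum(axis=1)

    value_cols = [c for c in per_cell.columns if c not in ("location_id", "year")]
    long = per_cell.melt(
        id_vars=["location_id", "year"], value_vars=value_cols,
        var_name="nutrient_id", value_name="value",
    )
    long["unit"] = long["nutrient_id"].map(nutrient_unit)
    long["lower"] = np.nan
    long["upper"] = np.nan
    long["observed"] = True
    return long[PANEL_COLUMNS].sort_values(["nutrient_id", "location_id", "year"]).reset_index(
        drop=True
    )


def validate_panel(panel: pd.DataFrame) -> None:
    """Check panel schema and value/bound invariants."""
    missing = set(PANEL_COLUMNS[:5]) - set(panel.columns)
    if missing:
        raise SchemaError(f"panel missing columns: {sorted(missing)}")
    if (panel["value"] < 0).any():
        raise DomainError("panel contains negative availability values")
    if {"lower", "upper"} <= set(panel.columns):
        bounded = panel.dropna(subset=["lower", "upper"])
        bad = (bounded["lower"] > bounded["value"]) | (bounded["value"] > bounded["upper"])
        if bad.any():
            raise DomainError("panel has cells with value outside [lower, upper]")
    per_nutrient = panel.groupby("nutrient_id")["unit"].nunique()
    mixed = per_nutrient[per_nutrient > 1]
    if len(mixed):
        raise UnitMismatchError(f"nutrients with inconsistent units: {list(mixed.index)}")


def add_panels(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    """Element-wise sum of two panels over shared (location, year, nutrient) keys.

    Unit discipline is enforced: adding entries whose units differ raises
    :class:`UnitMismatchError` rather than silently mixing scales.
    """
    keys = ["location_id", "year", "nutrient_id"]
    merged = left.merge(right, on=keys, suffixes=("_l", "_r"))
    clash = merged["unit_l"] != merged["unit_r"]
    if clash.any():
        pairs = merged.loc[clash, keys + ["unit_l", "unit_r"]].head(5)
        raise UnitMismatchError(f"unit mismatch when adding panels:\n{pairs}")
    out = merged[keys].copy()
    out["value"] = merged["value_l"] + merged["value_r"]
    out["unit"] = merged["unit_l"]
    out["lower"] = np.nan
    out["upper"] = np.nan
    out["observed"] = merged.get("observed_l", True) & merged.get("observed_r", True)
    return out[PANEL_COLUMNS]


def energy_shares(panel: pd.DataFrame, location_id, year) -> dict[str, float]:
    """Percentage of total energy from each macronutrient in one panel cell.

    Returns a mapping macronutrient -> percent for every ``*_kcal`` entry
    present (including the MUFA/PUFA/SFA fat sub-shares).  When the cell's
    energy is the Atwater total of its macronutrients, the four primary
    shares (carbohydrate, protein, fat, alcohol) sum to exactly 100.
    """
    cell = panel[(panel["location_id"] == location_id) & (panel["year"] == year)]
    if cell.empty:
        raise SchemaError(f"no panel entries for ({location_id!r}, {year})")
    values = cell.set_index("nutrient_id")["value"]
    if "energy_kcal" not in values.index:
        raise SchemaError(f"cell ({location_id!r}, {year}) has no energy_kcal entry")
    energy = float(values["energy_kcal"])
    if energy <= 0:
        raise UndefinedStatisticError(
            f"energy is {energy} for ({location_id!r}, {year}); shares undefined"
        )
    return {
        nid[: -len("_kcal")]: float(val) / energy * 100.0
        for nid, val in values.items()
        if nid.endswith("_kcal") and nid != "energy_kcal"
    }


def energy_shares_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Wide table of macronutrient energy shares (%) per location-year.

    Rows with nonpositive total energy are dropped.
    """
    wide = panel.pivot_table(
        index=["location_id", "year"], columns="nutrient_id", values="value", aggfunc="first"
    )
    if "energy_kcal" not in wide.columns:
        raise SchemaError("panel has no energy_kcal nutrient")
    wide = wide[wide["energy_kcal"] > 0]
    kcal_cols = [c for c in wide.columns if c.endswith("_kcal") and c != "energy_kcal"]
    shares = wide[kcal_cols].div(wide["energy_kcal"], axis=0) * 100.0
    shares.columns = [c[: -len("_kcal")] for c in kcal_cols]
    return shares.reset_index()
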