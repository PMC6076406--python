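"""Food-composition ledger: refuse adjustment, Atwater energy, carbohydrate by difference.

The ledger works per 100 g of *edible* portion.  A gross (as-purchased)
quantity is first reduced by the item's refuse factor — the inedible share
(bones, peel, shells) — before any nutrient arithmetic.  Energy follows the
Atwater metabolizable-energy convention (4 kcal/g protein, 4 kcal/g
carbohydrate, 9 kcal/g fat, 7 kcal/g alcohol), and digestible carbohydrate is
recovered "by difference": the energy not explained by protein, fat and
alcohol, divided by 4.  Carbohydrate by difference deliberately excludes
indigestible fibre, which contributes no metabolizable energy.

Refuse factors are properties of the food item alone: the schema has no
country or year dimension for them.
"""

from __future__ import annotations

import logging
import numbers
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

logger = logging.getLogger(__name__)

#: kcal per gram of protein, carbohydrate, fat, alcohol.
ATWATER_KCAL_PER_G = {"protein": 4.0, "carbohydrate": 4.0, "fat": 9.0, "alcohol": 7.0}

#: Numerical slack allowed when checking that fat subtypes sum to total fat.
FAT_SPLIT_TOL = 1e-6

#: Core macronutrient columns of a composition table (g per 100 g edible).
MACRO_COLUMNS = ("protein_g", "fat_g", "mufa_g", "pufa_g", "sfa_g", "alcohol_g")


@dataclass(frozen=True)
class CompositionRecord:
    """Nutrient composition of one food item, per 100 g edible portion.

    ``energy_kcal_per100g`` is the stored total energy.  It need not equal
    the Atwater sum of the macronutrients exactly (real composition tables
    carry rounding artefacts); carbohydrate by difference is defined against
    the stored energy.
    """

    item_id: str
    refuse_fraction: float
    energy_kcal_per100g: float
    protein_g: float
    fat_g: float
    mufa_g: float = 0.0
    pufa_g: float = 0.0
    sfa_g: float = 0.0
    alcohol_g: float = 0.0
    micronutrients: Mapping[str, tuple[float, str]] = field(default_factory=dict)

    def validate(self) -> None:
        """Raise :class:`DomainError` if any invariant is violated."""
        if not 0.0 <= self.refuse_fraction <= 1.0:
            raise DomainError(
                f"item {self.item_id!r}: refuse_fraction {self.refuse_fraction} outside [0, 1]"
            )
        for name in ("energy_kcal_per100g",) + tuple(MACRO_COLUMNS):
            attr = name if hasattr(self, name) else name
            value = getattr(self, attr)
            if value < 0:
                raise DomainError(f"item {self.item_id!r}: {name} is negative ({value})")
        if self.mufa_g + self.pufa_g + self.sfa_g > self.fat_g + FAT_SPLIT_TOL:
            raise DomainError(
                f"item {self.item_id!r}: fat subtypes sum to "
                f"{self.mufa_g + self.pufa_g + self.sfa_g:.6g} g, exceeding total fat "
                f"{self.fat_g:.6g} g"
            )
        for nutrient, (amount, _unit) in self.micronutrients.items():
            if amount < 0:
                raise DomainError(
                    f"item {self.item_id!r}: micronutrient {nutrient!r} is negative"
                )


def edible_fraction_mass(gross_g_per_person_day, refuse_fraction):
    """Mass remaining after removing the inedible (refuse) share.

    Parameters
    ----------
    gross_g_per_person_day
        Gross (as-purchased) mass rate, scalar or array, >= 0.
    refuse_fraction
        Inedible proportion in [0, 1], scalar or array.

    Returns
    -------
    Edible mass rate, ``gross * (1 - refuse)``, with the input's shape.
    """
    gross = np.asarray(gross_g_per_person_day, dtype=float)
    refuse = np.asarray(refuse_fraction, dtype=float)
    if np.any(gross < 0):
        raise DomainError("gross mass must be nonnegative")
    if np.any((refuse < 0) | (refuse > 1)):
        raise DomainError("refuse_fraction must lie in [0, 1]")
    out = gross * (1.0 - refuse)
    if np.isscalar(gross_g_per_person_day) or isinstance(
        gross_g_per_person_day, numbers.Number
    ):
        return float(out)
    return out


def atwater_energy(protein_g, carbohydrate_g, fat_g, alcohol_g=0.0):
    """Metabolizable energy (kcal) of given macronutrient masses (g).

    Applies the Atwater factors 4/4/9/7 kcal per g of protein, carbohydrate,
    fat, and alcohol.  Inputs may be scalars or arrays; negative values raise.
    """
    parts = {
        "protein": protein_g,
        "carbohydrate": carbohydrate_g,
        "fat": fat_g,
        "alcohol": alcohol_g,
    }
    total = None
    scalar = True
    for name, grams in parts.items():
        arr = np.asarray(grams, dtype=float)
        if np.any(arr < 0):
            raise DomainError(f"{name} mass must be nonnegative")
        scalar = scalar and arr.ndim == 0
        term = ATWATER_KCAL_PER_G[name] * arr
        total = term if total is None else total + term
    return float(total) if scalar else total


def carbohydrate_by_difference(record: CompositionRecord) -> float:
    """Digestible carbohydrate (g per 100 g edible) inferred from stored energy.

    ``(energy - 4*protein - 9*fat - 7*alcohol) / 4``, clamped at zero.  The
    clamp handles real-world composition rows whose stored energy is not an
    exact Atwater sum; a negative digestible carbohydrate is meaningless, so
    the value is floored at 0 and a warning is logged with the item id.
    """
    record.validate()
    non_carb_kcal = (
        ATWATER_KCAL_PER_G["protein"] * record.protein_g
        + ATWATER_KCAL_PER_G["fat"] * record.fat_g
        + ATWATER_KCAL_PER_G["alcohol"] * record.alcohol_g
    )
    carb = (record.energy_kcal_per100g - non_carb_kcal) / ATWATER_KCAL_PER_G["carbohydrate"]
    if carb < 0:
        logger.warning(
            "item %s: carbohydrate by difference is negative (%.4g g); clamping to 0",
            record.item_id,
            carb,
        )
        return 0.0
    return carb


def carbohydrate_by_difference_table(composition: pd.DataFrame) -> pd.Series:
    """Vectorised carbohydrate by difference over a composition table.

    Expects columns ``energy_kcal, protein_g, fat_g, alcohol_g`` (alcohol
    optional, treated as 0 when absent).  Negative results are clamped to 0
    with one warning listing the offending item ids.
    """
    required = {"energy_kcal", "protein_g", "fat_g"}
    missing = required - set(composition.columns)
    if missing:
        raise SchemaError(f"composition table missing columns: {sorted(missing)}")
    alcohol = composition.get("alcohol_g", 0.0)
    carb = (
        composition["energy_kcal"]
        - 4.0 * composition["protein_g"]
        - 9.0 * composition["fat_g"]
        - 7.0 * alcohol
    ) / 4.0
    negative = carb < 0
    if negative.any():
        ids = composition.loc[negative, "item_id"].tolist() if "item_id" in composition else list(
            composition.index[negative]
        )
        logger.warning(
            "carbohydrate by difference negative for %d items (clamped to 0): %s",
            int(negative.sum()),
            ids[:20],
        )
        carb = carb.clip(lower=0.0)
    return carb.rename("carbohydrate_g")


@dataclass
class MatchReport:
    """Outcome of validating a supply-item -> composition-item matching table."""

    unmatched_supply: list
    dangling_composition: list
    disagreements: list

    @property
    def ok(self) -> bool:
        return not (self.unmatched_supply or self.dangling_composition)

    def summary(self) -> str:
        return (
            f"{len(self.unmatched_supply)} unmatched supply item(s), "
            f"{len(self.dangling_composition)} dangling composition reference(s), "
            f"{len(self.disagreements)} coder disagreement(s)"
        )


def validate_matching(
    match: pd.DataFrame,
    supply_items: Sequence,
    composition_table: pd.DataFrame,
    allow_unmatched: Sequence | None = None,
) -> MatchReport:
    """Check a matching table against the supply item list and composition table.

    The matching table emulates a dual-coder workflow: each supply item was
    matched to a composition record independently by two coders.  The
    validator reports, it does not resolve — disagreement resolution is a
    human step upstream of the pipeline.

    Parameters
    ----------
    match
        Columns ``supply_item_id, composition_item_id`` and optionally
        ``coder_a, coder_b`` holding each coder's independent match.
    supply_items
        All item ids appearing in the supply panel.
    composition_table
        Must carry an ``item_id`` column.
    allow_unmatched
        Supply items explicitly permitted to lack a match (dropped from the
        unmatched report).
    """
    if "supply_item_id" not in match.columns or "composition_item_id" not in match.columns:
        raise SchemaError(
            "matching table requires columns supply_item_id and composition_item_id"
        )
    if match["supply_item_id"].duplicated().any():
        dupes = match.loc[match["supply_item_id"].duplicated(), "supply_item_id"].tolist()
        raise SchemaError(f"duplicate supply_item_id rows in matching table: {dupes[:10]}")
    allow = set(allow_unmatched or ())
    matched = set(match["supply_item_id"])
    unmatched = sorted(set(supply_items) - matched - allow)
    known = set(composition_table["item_id"])
    dangling = sorted(set(match["composition_item_id"]) - known)
    disagreements = []
    if "coder_a" in match.columns and "coder_b" in match.columns:
        both = match.dropna(subset=["coder_a", "coder_b"])
        mask = both["coder_a"] != both["coder_b"]
        disagreements = both.loc[mask, "supply_item_id"].tolist()
    return MatchReport(unmatched, dangling, disagreements)
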