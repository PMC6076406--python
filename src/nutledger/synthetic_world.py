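"""Synthetic supply-and-utilization worlds with known ground truth.

Real nutrient-availability databases are built from national food supply
ledgers (per-commodity, per-country, per-year), a food-composition table, and
dietary-recall surveys — none of which can ship with a package.  This module
generates internally consistent stand-ins with the same statistical
structure, so every downstream stage (accounting, gap-filling, SDI
aggregation, intake modelling) is testable against a known answer:

* composition rows whose stored energy is the exact Atwater sum of the
  generated macronutrients, making carbohydrate-by-difference invertible;
* locations on a development continuum that rises over time, with the item
  mix shifting so the carbohydrate energy share falls and the fat and
  protein shares rise with development (the secular "nutrition transition");
* country-year missingness, including optional whole-location gaps
  emulating countries with no supply ledger at all;
* covariates (income, education, fertility) tied monotonically to the
  development score;
* survey intake simulated from availability via a known slope, age/sex
  pattern, super-region intercepts, and a retail+household waste factor.

All randomness flows from the single root seed through named child streams
(``numpy`` ``SeedSequence`` spawn keys), so each generator is individually
and jointly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import ATWATER_KCAL_PER_G
from .errors import ConfigurationError, SchemaError

_STREAMS = {"development": 0, "composition": 1, "supply": 2, "covariates": 3, "intake": 4}

DEFAULT_AGE_GROUPS = ("2-19", "20-34", "35-49", "50-64", "65plus")
DEFAULT_SEXES = ("female", "male")

#: nutrient ids simulated in the survey-intake table by default
DEFAULT_INTAKE_NUTRIENTS = (
    "energy_kcal",
    "protein_kcal",
    "carbohydrate_kcal",
    "fat_kcal",
    "alcohol_kcal",
    "zinc_mg",
)

# Archetype -> (probability, mean g/100 g edible of protein/fat/carb/alcohol,
# refuse range).  Loosely shaped after cereal staples, produce, animal foods,
# oils/fats and alcoholic beverages.
_ARCHETYPES = {
    "staple": dict(p=0.35, protein=8.0, fat=2.0, carb=65.0, alcohol=0.0, refuse=(0.0, 0.15)),
    "produce": dict(p=0.20, protein=2.0, fat=0.5, carb=12.0, alcohol=0.0, refuse=(0.10, 0.60)),
    "animal": dict(p=0.20, protein=18.0, fat=12.0, carb=1.0, alcohol=0.0, refuse=(0.20, 0.50)),
    "fat_oil": dict(p=0.15, protein=1.0, fat=85.0, carb=1.0, alcohol=0.0, refuse=(0.0, 0.05)),
    "alcohol": dict(p=0.10, protein=0.5, fat=0.0, carb=4.0, alcohol=5.0, refuse=(0.0, 0.0)),
}

# Micronutrient density means (per 100 g edible) by archetype.
_MICRO_MEANS = {
    "iron_mg": {"staple": 2.5, "produce": 1.0, "animal": 2.0, "fat_oil": 0.1, "alcohol": 0.1},
    "zinc_mg": {"staple": 1.5, "produce": 0.4, "animal": 3.5, "fat_oil": 0.1, "alcohol": 0.05},
    "vita_rae_ug": {"staple": 5.0, "produce": 80.0, "animal": 40.0, "fat_oil": 30.0, "alcohol": 1.0},
}


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of one synthetic world.

    ``missing_fraction`` masks location-years at random;
    ``n_unobserved_locations`` additionally blanks whole locations, emulating
    countries with no supply ledger that must be predicted from covariates
    alone.  ``waste_factor`` is the retail+household waste share applied when
    deriving intake from availability; energy *shares* are invariant to it.
    ``beta`` is the structural intake slope before waste, so the slope
    relating simulated intake to availability is ``beta * (1 -
    waste_factor)`` (stored as ``GroundTruth.true_beta``).
    """

    n_items: int = 100
    n_locations: int = 150
    year_start: int = 1980
    year_end: int = 2013
    n_super_regions: int = 7
    missing_fraction: float = 0.2
    n_unobserved_locations: int = 0
    waste_factor: float = 0.3
    supply_noise_sd: float = 0.05
    beta: float = 1.0
    intake_noise_cv: float = 0.10
    age_groups: tuple = DEFAULT_AGE_GROUPS
    sexes: tuple = DEFAULT_SEXES
    seed: int = 0

    def validate(self) -> None:
        if self.n_items < 5:
            raise ConfigurationError(f"n_items must be >= 5, got {self.n_items}")
        if self.n_locations < 10:
            raise ConfigurationError(f"n_locations must be >= 10, got {self.n_locations}")
        if self.year_end - self.year_start + 1 < 2:
            raise ConfigurationError(
                f"years must span >= 2, got {self.year_start}..{self.year_end}"
            )
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigurationError(
                f"missing_fraction must lie in [0, 1), got {self.missing_fraction}"
            )
        if not 0.0 <= self.waste_factor < 1.0:
            raise ConfigurationError(f"waste_factor must lie in [0, 1), got {self.waste_factor}")
        if self.n_super_regions < 1:
            raise ConfigurationError(f"n_super_regions must be >= 1, got {self.n_super_regions}")
        if self.supply_noise_sd < 0:
            raise ConfigurationError(f"supply_noise_sd must be >= 0, got {self.supply_noise_sd}")
        if self.n_unobserved_locations < 0 or self.n_unobserved_locations >= self.n_locations:
            raise ConfigurationError(
                "n_unobserved_locations must be in [0, n_locations), got "
                f"{self.n_unobserved_locations}"
            )

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def location_ids(self) -> list[str]:
        return [f"loc_{i:03d}" for i in range(self.n_locations)]

    @property
    def item_ids(self) -> list[str]:
        return [f"item_{i:03d}" for i in range(self.n_items)]


@dataclass
class GroundTruth:
    """Everything the generators know that the pipeline must recover."""

    true_item_compositions: pd.DataFrame | None = None
    true_supply_panel: pd.DataFrame | None = None
    true_availability_panel: pd.DataFrame | None = None
    dev_scores: pd.DataFrame | None = None
    super_regions: pd.Series | None = None
    trend: dict = field(default_factory=dict)
    true_beta: float | None = None
    beta_raw: float | None = None
    waste_factor: float | None = None
    true_age_sex_pattern: pd.DataFrame | None = None
    age_effects: dict = field(default_factory=dict)
    sex_effects: dict = field(default_factory=dict)
    super_region_intercepts: dict = field(default_factory=dict)
    intake_noise_sd: dict = field(default_factory=dict)


def _rng(config: WorldConfig, stream: str) -> np.random.Generator:
    """Child generator for a named stream of the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],))
    )


def development_scores(config: WorldConfig) -> pd.DataFrame:
    """Development score per location-year, rising over time, in (0, 1).

    Base scores are evenly spaced and randomly assigned to locations; each
    location then closes 30% of its remaining gap to 1 over the study period,
    which preserves the cross-location ordering in every year.
    """
    config.validate()
    rng = _rng(config, "development")
    base = np.linspace(0.05, 0.95, config.n_locations)
    base = base[rng.permutation(config.n_locations)]
    years = config.years
    frac = (years - config.year_start) / max(1, config.year_end - config.year_start)
    dev = base[:, None] + (1.0 - base[:, None]) * 0.3 * frac[None, :]
    out = pd.DataFrame(
        {
            "location_id": np.repeat(config.location_ids, len(years)),
            "year": np.tile(years, config.n_locations),
            "dev": dev.ravel(),
        }
    )
    out["base_dev"] = np.repeat(base, len(years))
    return out


def super_region_assignment(config: WorldConfig) -> pd.Series:
    """Round-robin partition of locations into super-regions by development rank.

    Each super-region spans the whole development continuum, which gives the
    smoothing and intake stages exchangeable spatial blocks without a real
    geographic hierarchy.
    """
    dev = development_scores(config)
    base = dev.drop_duplicates("location_id").set_index("location_id")["base_dev"]
    rank = base.rank(method="first").astype(int) - 1
    sr = (rank % config.n_super_regions).map(lambda k: f"sr_{k}")
    sr.name = "super_region"
    return sr


def generate_composition_table(
    config: WorldConfig, macro_scale: float = 1.0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a composition table with Atwater-consistent stored energy.

    Every row's ``energy_kcal`` is set forward as ``4P + 9F + 4C + 7A``, so
    carbohydrate-by-difference recovers the generated digestible carbohydrate
    exactly.  The carbohydrate column itself is *not* in the returned table —
    it lives in ``GroundTruth.true_item_compositions`` — mirroring real
    composition sources where digestible carbohydrate is derived, not stored.

    ``macro_scale`` scales all macronutrient density means (0 gives an
    all-zero, zero-energy table for degenerate-case testing).
    """
    config.validate()
    if macro_scale < 0:
        raise ConfigurationError(f"macro_scale must be >= 0, got {macro_scale}")
    rng = _rng(config, "composition")
    names = list(_ARCHETYPES)
    probs = np.array([_ARCHETYPES[a]["p"] for a in names])
    arch = rng.choice(names, size=config.n_items, p=probs / probs.sum())
    # Guarantee the archetypes driving the development shift are represented.
    arch[0], arch[1], arch[2] = "staple", "animal", "fat_oil"

    shape = 9.0  # gamma shape; cv = 1/3 keeps densities positive and plausible
    cols = {c: np.zeros(config.n_items) for c in ("protein_g", "fat_g", "carbohydrate_g", "alcohol_g")}
    refuse = np.zeros(config.n_items)
    micros = {m: np.zeros(config.n_items) for m in _MICRO_MEANS}
    for i, a in enumerate(arch):
        spec_a = _ARCHETYPES[a]
        for col, key in (
            ("protein_g", "protein"),
            ("fat_g", "fat"),
            ("carbohydrate_g", "carb"),
            ("alcohol_g", "alcohol"),
        ):
            mean = spec_a[key] * macro_scale
            cols[col][i] = rng.gamma(shape, mean / shape) if mean > 0 else 0.0
        lo, hi = spec_a["refuse"]
        refuse[i] = rng.uniform(lo, hi)
        for m, means in _MICRO_MEANS.items():
            micros[m][i] = rng.gamma(shape, means[a] / shape) if means[a] > 0 else 1e-3

    # Fat subtype split: Dirichlet over (mufa, pufa, sfa, other) keeps the
    # subtypes strictly below total fat.
    split = rng.dirichlet([3.0, 1.5, 3.0, 1.0], size=config.n_items)
    mufa = cols["fat_g"] * split[:, 0]
    pufa = cols["fat_g"] * split[:, 1]
    sfa = cols["fat_g"] * split[:, 2]

    energy = (
        ATWATER_KCAL_PER_G["protein"] * cols["protein_g"]
        + ATWATER_KCAL_PER_G["fat"] * cols["fat_g"]
        + ATWATER_KCAL_PER_G["carbohydrate"] * cols["carbohydrate_g"]
        + ATWATER_KCAL_PER_G["alcohol"] * cols["alcohol_g"]
    )

    table = pd.DataFrame(
        {
            "item_id": config.item_ids,
            "refuse_fraction": refuse,
            "energy_kcal": energy,
            "protein_g": cols["protein_g"],
            "fat_g": cols["fat_g"],
            "mufa_g": mufa,
            "pufa_g": pufa,
            "sfa_g": sfa,
            "alcohol_g": cols["alcohol_g"],
            **micros,
        }
    )
    truth = GroundTruth()
    truth.true_item_compositions = table.assign(
        carbohydrate_g=cols["carbohydrate_g"], archetype=arch
    )
    return table, truth


def identity_matching(config: WorldConfig) -> pd.DataFrame:
    """Matching table mapping each supply item to its own composition row.

    Both coder columns agree, emulating a resolved dual-coder match.
    """
    return pd.DataFrame(
        {
            "supply_item_id": config.item_ids,
            "composition_item_id": config.item_ids,
            "coder_a": config.item_ids,
            "coder_b": config.item_ids,
        }
    )


# Share of total dietary energy supplied by each archetype at the two ends
# of the development continuum: staple-heavy at the bottom, more animal food
# and added fats at the top.  This drives carbohydrate share down and fat and
# protein shares up with development (the nutrition transition).
_ENERGY_BUDGETS = {
    "low": {"staple": 0.72, "produce": 0.10, "animal": 0.12, "fat_oil": 0.04, "alcohol": 0.02},
    "high": {"staple": 0.40, "produce": 0.12, "animal": 0.34, "fat_oil": 0.10, "alcohol": 0.04},
}


def _mixture_weights(truth_comp: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Item energy-weight profiles for the low- and high-development diet mixes.

    Each archetype's energy budget is split over its items proportionally to
    their energy density; an archetype absent from the drawn item set has
    its budget redistributed.  A location at development ``d`` consumes the
    convex combination ``(1-d)u + dv``, so each macronutrient's energy share
    along the path is a ratio of two linear functions of ``d`` and hence
    monotone in ``d``.
    """
    e_item = truth_comp["energy_kcal"].to_numpy()
    arch = truth_comp["archetype"].to_numpy()
    out = []
    for end in ("low", "high"):
        budgets = _ENERGY_BUDGETS[end]
        w = np.zeros(len(truth_comp))
        for a, budget in budgets.items():
            members = arch == a
            total = e_item[members].sum()
            if total > 0:
                w[members] = budget * e_item[members] / total
        out.append(w / w.sum())
    return out[0], out[1]


def _macro_shares_of_mix(truth_comp: pd.DataFrame, weights: np.ndarray) -> dict[str, float]:
    """Energy shares (%) of a diet mix given item energy weights."""
    e = truth_comp["energy_kcal"].to_numpy()
    total = float(weights @ e)
    shares = {}
    for macro, col, factor in (
        ("carbohydrate", "carbohydrate_g", 4.0),
        ("protein", "protein_g", 4.0),
        ("fat", "fat_g", 9.0),
        ("mufa", "mufa_g", 9.0),
        ("alcohol", "alcohol_g", 7.0),
    ):
        shares[macro] = float(weights @ (factor * truth_comp[col].to_numpy())) / total * 100.0
    return shares


def generate_supply_panel(
    config: WorldConfig,
    composition: pd.DataFrame,
    truth: GroundTruth | None = None,
    supply_noise_sd: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Per-item gross supply (g/person/day) per location-year, plus missingness.

    Total energy scales with development (~1900 kcal at the bottom of the
    continuum to ~3300 at the top) and the item mix moves from the
    carbohydrate-tilted to the fat/protein-tilted profile as development
    rises.  Quantities get multiplicative log-normal noise (supply ledgers
    are noisy but positive).  A ``missing_fraction`` Bernoulli mask plus
    optional whole-location gaps defines which cells the pipeline observes.

    Returns ``(observed supply rows, mask, truth)`` where the mask has one
    row per location-year with an ``observed`` flag, and ``truth`` gains the
    complete (unmasked) supply and availability panels.
    """
    config.validate()
    truth = truth or GroundTruth()
    if len(composition) != config.n_items:
        raise ConfigurationError(
            f"composition has {len(composition)} items, config expects {config.n_items}"
        )
    comp_truth = truth.true_item_compositions
    if comp_truth is None or len(comp_truth) != config.n_items:
        raise ConfigurationError(
            "ground truth composition missing or wrong size; generate the "
            "composition table first"
        )
    noise_sd = config.supply_noise_sd if supply_noise_sd is None else supply_noise_sd

    dev = development_scores(config)
    truth.dev_scores = dev
    truth.super_regions = super_region_assignment(config)
    u, v = _mixture_weights(comp_truth)
    truth.trend = {
        "low_dev_shares": _macro_shares_of_mix(comp_truth, u),
        "high_dev_shares": _macro_shares_of_mix(comp_truth, v),
        "energy_low_dev_kcal": 1900.0,
        "energy_high_dev_kcal": 3300.0,
    }

    d = dev["dev"].to_numpy()  # (n_cells,) ordered by location then year
    n_cells = len(d)
    total_energy = 1900.0 + 1400.0 * d
    w = (1.0 - d)[:, None] * u[None, :] + d[:, None] * v[None, :]  # (cells, items)
    item_energy = total_energy[:, None] * w
    e_item = comp_truth["energy_kcal"].to_numpy()
    refuse = comp_truth["refuse_fraction"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        edible_g = np.where(e_item > 0, 100.0 * item_energy / e_item, 0.0)
    gross = edible_g / (1.0 - refuse)

    rng = _rng(config, "supply")
    if noise_sd > 0:
        gross = gross * np.exp(rng.normal(0.0, noise_sd, size=gross.shape))
    else:
        rng.normal(0.0, 1.0, size=gross.shape)  # keep stream alignment across noise settings

    full = pd.DataFrame(
        {
            "location_id": np.repeat(dev["location_id"].to_numpy(), config.n_items),
            "year": np.repeat(dev["year"].to_numpy(), config.n_items),
            "item_id": np.tile(config.item_ids, n_cells),
            "gross_supply_g_per_person_day": gross.ravel(),
        }
    )
    truth.true_supply_panel = full
    truth.true_availability_panel = _availability_from_supply(full, comp_truth)

    observed = rng.random(n_cells) >= config.missing_fraction
    if config.n_unobserved_locations > 0:
        gone = rng.choice(
            config.location_ids, size=config.n_unobserved_locations, replace=False
        )
        observed &= ~dev["location_id"].isin(gone).to_numpy()
    mask = pd.DataFrame(
        {"location_id": dev["location_id"], "year": dev["year"], "observed": observed}
    )
    keep = np.repeat(observed, config.n_items)
    supply = full.loc[keep].reset_index(drop=True)
    return supply, mask, truth


def _availability_from_supply(supply: pd.DataFrame, comp_truth: pd.DataFrame) -> pd.DataFrame:
    """Direct dense computation of the complete nutrient availability panel.

    Uses the generator's forward carbohydrate (no by-difference step); the
    accounting engine must reproduce this panel from the same rows.
    """
    from .availability import PANEL_COLUMNS, nutrient_unit

    density_cols = [
        "protein_g", "fat_g", "mufa_g", "pufa_g", "sfa_g", "alcohol_g",
        "carbohydrate_g", "iron_mg", "zinc_mg", "vita_rae_ug",
    ]
    comp = comp_truth.set_index("item_id")
    items = supply["item_id"].to_numpy()
    refuse = comp["refuse_fraction"].reindex(items).to_numpy()
    edible = supply["gross_supply_g_per_person_day"].to_numpy() * (1.0 - refuse)
    dens = comp[density_cols].reindex(items).to_numpy()
    contrib = dens * edible[:, None] / 100.0
    cell = (
        pd.DataFrame(contrib, columns=density_cols)
        .assign(location_id=supply["location_id"].to_numpy(), year=supply["year"].to_numpy())
        .groupby(["location_id", "year"], as_index=False, sort=True)
        .sum()
    )
    for macro, col, factor in (
        ("protein", "protein_g", 4.0),
        ("carbohydrate", "carbohydrate_g", 4.0),
        ("fat", "fat_g", 9.0),
        ("mufa", "mufa_g", 9.0),
        ("pufa", "pufa_g", 9.0),
        ("sfa", "sfa_g", 9.0),
        ("alcohol", "alcohol_g", 7.0),
    ):
        cell[f"{macro}_kcal"] = cell[col] * factor
    cell["energy_kcal"] = (
        cell["protein_kcal"] + cell["carbohydrate_kcal"] + cell["fat_kcal"] + cell["alcohol_kcal"]
    )
    long = cell.melt(id_vars=["location_id", "year"], var_name="nutrient_id", value_name="value")
    long["unit"] = long["nutrient_id"].map(nutrient_unit)
    long["lower"] = np.nan
    long["upper"] = np.nan
    long["observed"] = True
    return long[PANEL_COLUMNS].sort_values(
        ["nutrient_id", "location_id", "year"]
    ).reset_index(drop=True)


def generate_covariates(config: WorldConfig) -> pd.DataFrame:
    """Income, education, fertility, and population per location-year.

    All three development components are deterministic monotone functions of
    the development score (income rising and right-skewed, education rising,
    total fertility falling), with a common year-level shock on income so
    that lag-distribution has something to average.  Population is a
    location-level log-normal size with mild exponential growth.
    """
    config.validate()
    rng = _rng(config, "covariates")
    dev = development_scores(config)
    years = config.years
    eta = rng.normal(0.0, 0.03, size=len(years))  # common income shock per year
    eta_by_year = pd.Series(eta, index=years)
    pop0 = rng.lognormal(mean=15.0, sigma=1.0, size=config.n_locations)
    pop_by_loc = pd.Series(pop0, index=config.location_ids)
    sr = super_region_assignment(config)

    out = dev[["location_id", "year"]].copy()
    d = dev["dev"].to_numpy()
    out["income_per_capita"] = 450.0 * np.exp(3.2 * d) * np.exp(
        eta_by_year.reindex(dev["year"]).to_numpy()
    )
    out["education_years"] = 1.5 + 13.0 * d
    out["tfr"] = 7.5 * np.exp(-1.8 * d)
    growth = 1.008 ** (dev["year"].to_numpy() - config.year_start)
    out["population"] = pop_by_loc.reindex(dev["location_id"]).to_numpy() * growth
    out["super_region"] = sr.reindex(dev["location_id"]).to_numpy()
    return out


def default_age_sex_pattern(config: WorldConfig) -> pd.DataFrame:
    """Relative intake multipliers per (age group, sex), mean-1 at equal weights.

    Children eat less, working-age adults more, and men more than women —
    the broad shape of energy-intake patterns in dietary recall surveys.
    The same pattern is applied to every nutrient.
    """
    age_factors = dict(zip(DEFAULT_AGE_GROUPS, (0.75, 1.05, 1.10, 1.00, 0.90)))
    sex_factors = {"female": 0.85, "male": 1.15}
    rows = []
    for a in config.age_groups:
        for s in config.sexes:
            rows.append((a, s, age_factors.get(a, 1.0) * sex_factors.get(s, 1.0)))
    pattern = pd.DataFrame(rows, columns=["age_group", "sex", "multiplier"])
    pattern["multiplier"] /= pattern["multiplier"].mean()
    return pattern


def generate_survey_intake(
    config: WorldConfig,
    availability_panel: pd.DataFrame,
    pattern: pd.DataFrame | None = None,
    truth: GroundTruth | None = None,
    nutrients: Sequence[str] = DEFAULT_INTAKE_NUTRIENTS,
    super_regions: pd.Series | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate survey mean intake from the availability panel.

    For each (location, year, age, sex, nutrient):

    ``intake = beta * availability * pattern(a, s) * (1 - waste_factor)
    + age effect + sex effect + super-region intercept + noise``

    with the pattern normalised to mean 1 over groups (so national
    availability is conserved), additive effects scaled to each nutrient's
    mean availability, homoscedastic Gaussian noise with SD
    ``intake_noise_cv`` times the mean signal, and a floor at zero.
    """
    config.validate()
    truth = truth or GroundTruth()
    if pattern is None:
        pattern = default_age_sex_pattern(config)
    required = {(a, s) for a in config.age_groups for s in config.sexes}
    have = set(map(tuple, pattern[["age_group", "sex"]].itertuples(index=False)))
    if required - have:
        raise SchemaError(f"age/sex pattern missing cells: {sorted(required - have)}")
    if (pattern["multiplier"] <= 0).any():
        raise SchemaError("age/sex multipliers must be positive")
    pattern = pattern.copy()
    pattern["multiplier"] /= pattern["multiplier"].mean()

    if super_regions is None:
        super_regions = super_region_assignment(config)
    rng = _rng(config, "intake")
    sr_names = sorted(super_regions.unique())
    sr_coef = dict(zip(sr_names, rng.normal(0.0, 0.05, size=len(sr_names))))
    age_coef = dict(zip(config.age_groups, rng.normal(0.0, 0.03, size=len(config.age_groups))))
    sex_coef = dict(zip(config.sexes, rng.normal(0.0, 0.02, size=len(config.sexes))))

    beta_eff = config.beta * (1.0 - config.waste_factor)
    frames = []
    for nutrient in nutrients:
        cells = availability_panel[availability_panel["nutrient_id"] == nutrient]
        if cells.empty:
            raise SchemaError(f"availability panel has no nutrient {nutrient!r}")
        scale = float(cells["value"].mean())
        grid = cells.merge(pattern, how="cross")
        signal = beta_eff * grid["value"].to_numpy() * grid["multiplier"].to_numpy()
        offsets = (
            grid["age_group"].map(age_coef).to_numpy(dtype=float)
            + grid["sex"].map(sex_coef).to_numpy(dtype=float)
            + grid["location_id"].map(super_regions).map(sr_coef).to_numpy(dtype=float)
        ) * scale
        noise_sd = config.intake_noise_cv * float(np.mean(signal)) if config.intake_noise_cv > 0 else 0.0
        noise = rng.normal(0.0, noise_sd, size=len(grid)) if noise_sd > 0 else 0.0
        intake = np.clip(signal + offsets + noise, 0.0, None)
        frames.append(
            pd.DataFrame(
                {
                    "location_id": grid["location_id"].to_numpy(),
                    "year": grid["year"].to_numpy(),
                    "age_group": grid["age_group"].to_numpy(),
                    "sex": grid["sex"].to_numpy(),
                    "nutrient_id": nutrient,
                    "mean_intake": intake,
                }
            )
        )
        truth.intake_noise_sd[nutrient] = noise_sd
        truth.age_effects[nutrient] = {a: c * scale for a, c in age_coef.items()}
        truth.sex_effects[nutrient] = {s: c * scale for s, c in sex_coef.items()}
        truth.super_region_intercepts[nutrient] = {r: c * scale for r, c in sr_coef.items()}

    truth.true_beta = beta_eff
    truth.beta_raw = config.beta
    truth.waste_factor = config.waste_factor
    truth.true_age_sex_pattern = pattern
    return pd.concat(frames, ignore_index=True), truth


@dataclass
class World:
    """One fully generated synthetic study world."""

    config: WorldConfig
    composition: pd.DataFrame
    matching: pd.DataFrame
    supply: pd.DataFrame
    mask: pd.DataFrame
    covariates: pd.DataFrame
    intake: pd.DataFrame
    ground_truth: GroundTruth


def generate_world(
    config: WorldConfig, intake_nutrients: Sequence[str] = DEFAULT_INTAKE_NUTRIENTS
) -> World:
    """Generate all five tables of a synthetic world plus its ground truth."""
    composition, truth = generate_composition_table(config)
    supply, mask, truth = generate_supply_panel(config, composition, truth)
    covariates = generate_covariates(config)
    intake, truth = generate_survey_intake(
        config,
        truth.true_availability_panel,
        truth=truth,
        nutrients=intake_nutrients,
        super_regions=truth.super_regions,
    )
    return World(
        config=config,
        composition=composition,
        matching=identity_matching(config),
        supply=supply,
        mask=mask,
        covariates=covariates,
        intake=intake,
        ground_truth=truth,
    )


def write_world(world: World, out_dir) -> None:
    """Write the world's tables as UTF-8 CSVs plus a ground-truth JSON."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world.supply.to_csv(out / "supply.csv", index=False)
    world.composition.to_csv(out / "composition.csv", index=False)
    world.matching.to_csv(out / "matching.csv", index=False)
    world.covariates.to_csv(out / "covariates.csv", index=False)
    world.intake.to_csv(out / "intake.csv", index=False)
    world.mask.to_csv(out / "mask.csv", index=False)
    truth = world.ground_truth
    truth.true_availability_panel.to_csv(out / "true_availability.csv", index=False)
    payload = {
        "seed": world.config.seed,
        "true_beta": truth.true_beta,
        "beta_raw": truth.beta_raw,
        "waste_factor": truth.waste_factor,
        "trend": truth.trend,
        "age_effects": truth.age_effects,
        "sex_effects": truth.sex_effects,
        "super_region_intercepts": truth.super_region_intercepts,
        "intake_noise_sd": truth.intake_noise_sd,
        "age_sex_pattern": truth.true_age_sex_pattern.to_dict(orient="records"),
    }
    (out / "ground_truth.json").write_text(json.dumps(payload, indent=2))
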