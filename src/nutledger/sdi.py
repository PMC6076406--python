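"""Socio-demographic index (SDI) construction and development-level aggregation.

SDI summarises a location's development as the geometric mean of three
components, each min-max rescaled to [0, 1] over the entire study period
pooled across locations: lag-distributed income per capita (higher is
better), mean educational attainment in the population over 15 (higher is
better), and total fertility rate (lower is better, so its scale is
inverted).  Quintiles of SDI define five development levels, and
availability series are aggregated within levels by population weighting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, UndefinedStatisticError
from .stgpr import lag_distributed_income

LEVELS = ("low", "lower-middle", "middle", "upper-middle", "high")


def rescale_component(values, direction: str = "ascending") -> np.ndarray:
    """Min-max rescale pooled values to [0, 1].

    ``direction='ascending'`` maps the observed minimum to 0 and maximum to
    1 (income, education); ``'descending'`` inverts the scale (total
    fertility, where the lowest observed value is best).
    """
    x = np.asarray(values, dtype=float)
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        raise UndefinedStatisticError("constant component series: min-max rescale undefined")
    scaled = (x - lo) / (hi - lo)
    if direction == "descending":
        return 1.0 - scaled
    if direction != "ascending":
        raise DomainError(f"direction must be 'ascending' or 'descending', got {direction!r}")
    return scaled


def compute_sdi(income_scaled, education_scaled, tfr_scaled) -> np.ndarray:
    """Geometric mean of the three rescaled components; 0 if any is 0."""
    comps = np.stack(
        [np.asarray(c, dtype=float) for c in (income_scaled, education_scaled, tfr_scaled)]
    )
    if np.any(comps < 0):
        raise DomainError("rescaled components must be nonnegative")
    return np.cbrt(comps[0] * comps[1] * comps[2])


def sdi_from_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """SDI per location-year from a raw covariate panel.

    Computes lag-distributed income from ``income_per_capita`` (unless an
    ``ldi`` column is already present), rescales all three components over
    the pooled study period, and returns ``location_id, year, sdi``.
    """
    required = {"location_id", "year", "education_years", "tfr"}
    if missing := required - set(covariates.columns):
        raise SchemaError(f"covariates missing columns: {sorted(missing)}")
    cov = covariates.copy()
    if "ldi" not in cov.columns:
        cov = cov.merge(
            lag_distributed_income(cov[["location_id", "year", "income_per_capita"]]),
            on=["location_id", "year"],
        )
    out = cov[["location_id", "year"]].copy()
    out["sdi"] = compute_sdi(
        rescale_component(cov["ldi"], "ascending"),
        rescale_component(cov["education_years"], "ascending"),
        rescale_component(cov["tfr"], "descending"),
    )
    return out


def assign_quintiles(sdi: pd.Series) -> pd.Series:
    """Development level per location from its SDI at a reference year.

    Rank-based quintiles: locations are sorted by SDI (ties broken by
    location id, lexicographically) and split into five contiguous blocks
    whose sizes differ by at most one; higher SDI never gets a lower level.

    Parameters
    ----------
    sdi
        SDI values indexed by location_id.
    """
    if len(sdi) < 5:
        raise SchemaError(f"need >= 5 locations for quintiles, got {len(sdi)}")
    order = sdi.reset_index()
    order.columns = ["location_id", "sdi"]
    order = order.sort_values(["sdi", "location_id"]).reset_index(drop=True)
    n = len(order)
    level_idx = (np.arange(n) * 5) // n
    out = pd.Series(
        pd.Categorical.from_codes(level_idx, categories=list(LEVELS), ordered=True),
        index=order["location_id"],
        name="level",
    )
    return out.reindex(sdi.index)


def aggregate_by_level(
    panel: pd.DataFrame, quintiles: pd.Series, population: pd.DataFrame
) -> pd.DataFrame:
    """Population-weighted mean availability per development level and globally.

    Parameters
    ----------
    panel
        Long nutrient panel (``location_id, year, nutrient_id, value``).
    quintiles
        location_id -> level (fixed across years for trend reporting).
    population
        ``location_id, year, population``.

    Returns
    -------
    Long table ``scope, nutrient_id, year, value`` where scope is each level
    plus ``global``; values are per-person (population-weighted means).
    """
    if missing := {"location_id", "year", "population"} - set(population.columns):
        raise SchemaError(f"population table missing columns: {sorted(missing)}")
    merged = panel.merge(population[["location_id", "year", "population"]],
                         on=["location_id", "year"], how="left")
    if merged["population"].isna().any():
        bad = merged.loc[merged["population"].isna(), "location_id"].unique()[:5]
        raise SchemaError(f"missing population for locations {list(bad)}")
    merged["level"] = merged["location_id"].map(quintiles)
    if merged["level"].isna().any():
        bad = merged.loc[merged["level"].isna(), "location_id"].unique()[:5]
        raise SchemaError(f"locations without a development level: {list(bad)}")

    def _wmean(g: pd.DataFrame) -> float:
        return float(np.average(g["value"], weights=g["population"]))

    per_level = (
        merged.groupby(["level", "nutrient_id", "year"], observed=True)
        .apply(_wmean, include_groups=False)
        .rename("value")
        .reset_index()
        .rename(columns={"level": "scope"})
    )
    global_agg = (
        merged.groupby(["nutrient_id", "year"])
        .apply(_wmean, include_groups=False)
        .rename("value")
        .reset_index()
    )
    global_agg["scope"] = "global"
    out = pd.concat([per_level, global_agg], ignore_index=True)
    out["scope"] = out["scope"].astype(str)
    return out[["scope", "nutrient_id", "year", "value"]]
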