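"""Headline descriptive statistics: net changes and macronutrient substitution.

Two families of summaries: (a) absolute change of an availability series
between the first and last study years, and (b) cross-country Pearson
correlations between macronutrient energy shares (or absolute availabilities)
at a fixed year.  A strong negative share correlation — e.g. carbohydrate
share against monounsaturated-fat share — is the signature of macronutrient
substitution along the development continuum.

P-values are the standard two-sided t-transform of r and are reported
unadjusted; a zero-variance series makes the correlation undefined and is
flagged as NaN rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError


def absolute_change(series: pd.Series, year_start: int = 1980, year_end: int = 2013) -> float:
    """``value(year_end) - value(year_start)`` of a year-indexed series."""
    for year in (year_start, year_end):
        if year not in series.index:
            raise SchemaError(f"series has no value for year {year}")
    return float(series.loc[year_end] - series.loc[year_start])


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with two-sided p-values.

    Pairs where either variable has zero variance are NaN in both ``r`` and
    ``p`` (undefined correlation), never silently zero.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def pair(self, a: str, b: str) -> tuple[float, float]:
        return float(self.r.loc[a, b]), float(self.p.loc[a, b])


def _pearson_matrix(data: pd.DataFrame) -> CorrelationMatrix:
    cols = list(data.columns)
    n = len(data)
    if n < 3:
        raise SchemaError(f"need >= 3 observations for correlations, got {n}")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=0)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            if sd[i] == 0 or sd[j] == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x[:, i], x[:, j])
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return CorrelationMatrix(r=r, p=p, n=n)


def share_correlation_matrix(shares: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson correlations of macronutrient energy shares.

    Parameters
    ----------
    shares
        One row per location, one column per macronutrient share (%), e.g.
        the output of :func:`nutledger.availability.energy_shares_table`
        restricted to one year (identifier columns are dropped if present).
    """
    data = shares.drop(columns=[c for c in ("location_id", "year") if c in shares.columns])
    return _pearson_matrix(data)


def availability_correlations(
    panel: pd.DataFrame, nutrients, year: int | None = None
) -> CorrelationMatrix:
    """Pairwise Pearson correlations of absolute availability across locations.

    ``year=None`` uses the final year in the panel (the cross-sectional
    default); pass a year to pick a different cross-section.
    """
    if year is None:
        year = int(panel["year"].max())
    sub = panel[(panel["year"] == year) & panel["nutrient_id"].isin(nutrients)]
    wide = sub.pivot_table(index="location_id", columns="nutrient_id", values="value",
                           aggfunc="first")
    missing = set(nutrients) - set(wide.columns)
    if missing:
        raise SchemaError(f"panel lacks nutrients {sorted(missing)} in year {year}")
    return _pearson_matrix(wide[list(nutrients)].dropna())


def trend_report(
    aggregated: pd.DataFrame, year_start: int = 1980, year_end: int = 2013
) -> pd.DataFrame:
    """Start/end values, net change, and energy shares per scope and nutrient.

    Parameters
    ----------
    aggregated
        Long table ``scope, nutrient_id, year, value`` (e.g. from
        :func:`nutledger.sdi.aggregate_by_level`); must include
        ``energy_kcal`` per scope for the share columns.
    """
    rows = []
    for scope, grp in aggregated.groupby("scope"):
        wide = grp.pivot_table(index="year", columns="nutrient_id", values="value",
                               aggfunc="first")
        energy = wide.get("energy_kcal")
        for nutrient in wide.columns:
            series = wide[nutrient]
            start, end = float(series.loc[year_start]), float(series.loc[year_end])
            share_start = share_end = np.nan
            if (
                energy is not None
                and nutrient.endswith("_kcal")
                and nutrient != "energy_kcal"
            ):
                share_start = start / float(energy.loc[year_start]) * 100.0
                share_end = end / float(energy.loc[year_end]) * 100.0
            rows.append(
                {
                    "scope": scope,
                    "nutrient_id": nutrient,
                    "value_start": start,
                    "value_end": end,
                    "net_change": end - start,
                    "share_start": share_start,
                    "share_end": share_end,
                }
            )
    return pd.DataFrame(rows)
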