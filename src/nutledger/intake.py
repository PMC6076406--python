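"""Bridge from national nutrient availability to individual-level intake.

Availability is what reaches the household; intake is what people eat.  The
bridge has three parts:

* **Age/sex disaggregation.**  A relative intake pattern (multiplier per age
  group and sex) splits a national per-capita value into group-level values,
  renormalised so the population-weighted mean over groups equals the
  national value — disaggregation never creates or destroys nutrients.
* **Intake regression.**  A linear model
  ``intake = beta * availability + age + sex + alpha_super_region``
  fitted by a mixed-effects regression with exchangeable super-region
  intercepts (fixed-effects fallback when the mixed fit cannot converge),
  plus pluggable tree-ensemble regressors behind the same fit/predict
  contract.
* **Validation.**  Out-of-sample RMSE and Pearson correlation under
  leave-locations-out (default), leave-years-out, or random holdout, and an
  energy-share comparison between availability and survey intake.  Shares
  are invariant to any uniform retail/household waste factor, which is what
  makes them the right validation currency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, UndefinedStatisticError

logger = logging.getLogger(__name__)

#: macronutrients compared in the energy-share validation
SHARE_MACROS = ("carbohydrate", "protein", "fat", "alcohol")

FEATURE_COLUMNS = ("availability", "age_group", "sex", "super_region")


def apply_age_sex_pattern(
    value: float,
    pattern: pd.DataFrame,
    weights: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Disaggregate a national per-capita value by age group and sex.

    Parameters
    ----------
    value
        National per-capita availability of one nutrient in one
        location-year.
    pattern
        Columns ``age_group, sex, multiplier`` (all positive), one row per
        group.
    weights
        Columns ``age_group, sex, weight`` giving population shares;
        defaults to equal weights.  The output satisfies
        ``sum(w * out) / sum(w) == value`` exactly: multipliers are used
        only as *relative* intakes.

    Returns
    -------
    ``age_group, sex, value`` with one row per pattern row.
    """
    if {"age_group", "sex", "multiplier"} - set(pattern.columns):
        raise SchemaError("pattern needs columns age_group, sex, multiplier")
    if (pattern["multiplier"] <= 0).any():
        raise SchemaError("pattern multipliers must be positive")
    merged = pattern.copy()
    if weights is None:
        merged["weight"] = 1.0
    else:
        merged = merged.merge(weights, on=["age_group", "sex"], how="left")
        if merged["weight"].isna().any():
            missing = merged.loc[merged["weight"].isna(), ["age_group", "sex"]]
            raise SchemaError(f"weights missing groups:\n{missing}")
        if (merged["weight"] < 0).any() or merged["weight"].sum() <= 0:
            raise DomainError("weights must be nonnegative with positive total")
    w = merged["weight"].to_numpy(dtype=float)
    m = merged["multiplier"].to_numpy(dtype=float)
    norm = float(w @ m) / w.sum()
    out = merged[["age_group", "sex"]].copy()
    out["value"] = value * m / norm
    return out


@dataclass
class IntakeModelFit:
    """Fitted coefficients of the availability-to-intake regression."""

    beta: float
    beta_se: float
    beta_ci: tuple[float, float]
    age_effects: dict
    sex_effects: dict
    super_region_effects: dict
    intercept: float
    residual_sd: float
    method: str  # "mixed" or "fixed"
    n_obs: int
    converged: bool = True

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predict intake for rows with the standard feature columns.

        Unseen super-regions get the average (zero) region effect.
        """
        out = self.intercept + self.beta * df["availability"].to_numpy(dtype=float)
        out = out + df["age_group"].map(self.age_effects).fillna(0.0).to_numpy(dtype=float)
        out = out + df["sex"].map(self.sex_effects).fillna(0.0).to_numpy(dtype=float)
        out = out + df["super_region"].map(self.super_region_effects).fillna(0.0).to_numpy(
            dtype=float
        )
        return out


def _check_fit_inputs(df: pd.DataFrame) -> None:
    if missing := ({"intake"} | set(FEATURE_COLUMNS)) - set(df.columns):
        raise SchemaError(f"fit table missing columns: {sorted(missing)}")
    if len(df) < 30:
        raise SchemaError(f"need >= 30 rows to fit the intake model, got {len(df)}")
    if df["super_region"].nunique() < 2:
        raise SchemaError("need >= 2 super-regions to separate region effects")
    if float(np.std(df["availability"])) == 0.0:
        raise DomainError("availability is constant: slope is collinear with the intercept")


def fit_intake_model(df: pd.DataFrame, method: str = "auto") -> IntakeModelFit:
    """Fit ``intake ~ availability + age + sex + super-region intercepts``.

    ``method='mixed'`` treats super-region as an exchangeable random
    intercept (restricted maximum likelihood); ``'fixed'`` uses super-region
    fixed effects estimated by ordinary least squares.  ``'auto'`` tries the
    mixed model and falls back to the fixed-effects fit if it fails to
    converge; the fit records which was used.  Age, sex, and region effects
    are centred so they represent deviations from the overall intercept.
    """
    import statsmodels.formula.api as smf

    if method not in ("auto", "mixed", "fixed"):
        raise DomainError(f"unknown method {method!r}")
    _check_fit_inputs(df)
    data = df.rename(columns={"mean_intake": "intake"}) if "intake" not in df.columns else df
    data = data.copy()

    formula = "intake ~ availability + C(age_group) + C(sex)"
    fit_method = method
    result = None
    if method in ("auto", "mixed"):
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = smf.mixedlm(formula, data, groups=data["super_region"]).fit(reml=True)
            if not np.all(np.isfinite(result.params)):
                raise ValueError("non-finite mixed-model coefficients")
            fit_method = "mixed"
        except Exception as err:  # pragma: no cover - depends on optimizer behaviour
            if method == "mixed":
                raise
            logger.info("mixed model failed (%s); falling back to fixed effects", err)
            result = None
    if result is None:
        result = smf.ols(formula + " + C(super_region)", data).fit()
        fit_method = "fixed"

    params = result.params
    beta = float(params["availability"])
    beta_se = float(result.bse["availability"])
    ci = result.conf_int()
    beta_ci = (float(ci.loc["availability", 0]), float(ci.loc["availability", 1]))

    def _level_effects(prefix: str, levels: Sequence) -> dict:
        effects = {}
        for level in levels:
            key = f"{prefix}[T.{level}]"
            effects[level] = float(params[key]) if key in params.index else 0.0
        mean = float(np.mean(list(effects.values())))
        return {k: v - mean for k, v in effects.items()}, mean

    age_effects, age_mean = _level_effects("C(age_group)", sorted(data["age_group"].unique()))
    sex_effects, sex_mean = _level_effects("C(sex)", sorted(data["sex"].unique()))

    if fit_method == "mixed":
        re = result.random_effects
        region_effects = {g: float(v.iloc[0]) for g, v in re.items()}
        region_mean = 0.0
        residual_sd = float(np.sqrt(result.scale))
        converged = bool(getattr(result, "converged", True))
    else:
        region_effects, region_mean = _level_effects(
            "C(super_region)", sorted(data["super_region"].unique())
        )
        residual_sd = float(np.sqrt(result.scale))
        converged = True

    intercept = float(params["Intercept"]) + age_mean + sex_mean + region_mean
    return IntakeModelFit(
        beta=beta,
        beta_se=beta_se,
        beta_ci=beta_ci,
        age_effects=age_effects,
        sex_effects=sex_effects,
        super_region_effects=region_effects,
        intercept=intercept,
        residual_sd=residual_sd,
        method=fit_method,
        n_obs=len(data),
        converged=converged,
    )


# --- regressor registry ----------------------------------------------------

REGRESSORS: dict[str, Callable[..., "IntakeRegressor"]] = {}


def register_regressor(name: str):
    """Register a factory under ``name`` for use in out-of-sample evaluation."""

    def deco(factory):
        REGRESSORS[name] = factory
        return factory

    return deco


class IntakeRegressor:
    """Fit/predict contract: ``fit(df)`` with `intake` + feature columns,
    ``predict(df)`` returning an array of intakes."""

    def fit(self, df: pd.DataFrame) -> "IntakeRegressor":
        raise NotImplementedError

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError


@register_regressor("linear")
class LinearIntakeRegressor(IntakeRegressor):
    """The mixed/fixed-effects linear model behind the registry contract."""

    def __init__(self, method: str = "auto", seed: int | None = None):
        self.method = method
        self.fit_result: IntakeModelFit | None = None

    def fit(self, df: pd.DataFrame) -> "LinearIntakeRegressor":
        self.fit_result = fit_intake_model(df, method=self.method)
        return self

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        if self.fit_result is None:
            raise RuntimeError("regressor not fitted")
        return self.fit_result.predict(df)


class _SklearnStyleRegressor(IntakeRegressor):
    """Shared feature encoding for tree ensembles: availability + year stay
    numeric, age/sex/super-region are one-hot with categories frozen at fit."""

    def __init__(self, model):
        self.model = model
        self.columns: list[str] | None = None

    def _encode(self, df: pd.DataFrame) -> pd.DataFrame:
        numeric = [c for c in ("availability", "year") if c in df.columns]
        x = pd.get_dummies(
            df[list(numeric) + ["age_group", "sex", "super_region"]],
            columns=["age_group", "sex", "super_region"],
        )
        if self.columns is None:
            self.columns = list(x.columns)
        return x.reindex(columns=self.columns, fill_value=0)

    def fit(self, df: pd.DataFrame) -> "_SklearnStyleRegressor":
        self.columns = None
        y = df["intake"] if "intake" in df.columns else df["mean_intake"]
        self.model.fit(self._encode(df), np.asarray(y, dtype=float))
        return self

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.model.predict(self._encode(df)), dtype=float)


@register_regressor("random_forest")
def _random_forest(seed: int | None = 0, **kwargs) -> IntakeRegressor:
    from sklearn.ensemble import RandomForestRegressor

    kwargs.setdefault("n_estimators", 100)
    return _SklearnStyleRegressor(RandomForestRegressor(random_state=seed, **kwargs))


@register_regressor("xgboost")
def _xgboost(seed: int | None = 0, **kwargs) -> IntakeRegressor:
    from xgboost import XGBRegressor

    kwargs.setdefault("n_estimators", 100)
    kwargs.setdefault("verbosity", 0)
    return _SklearnStyleRegressor(XGBRegressor(random_state=seed, **kwargs))


def make_regressor(name: str, seed: int | None = 0, **kwargs) -> IntakeRegressor:
    if name not in REGRESSORS:
        raise SchemaError(f"unknown regressor {name!r}; registered: {sorted(REGRESSORS)}")
    factory = REGRESSORS[name]
    try:
        return factory(seed=seed, **kwargs)
    except TypeError:
        return factory(**kwargs)


# --- out-of-sample evaluation ----------------------------------------------

HOLDOUT_SCHEMES = ("by-location", "by-year", "random")


@dataclass
class OOSMetrics:
    """Out-of-sample fit quality on one holdout split."""

    rmse: float
    r: float  # NaN when predictions are constant (correlation undefined)
    n_train: int
    n_test: int
    scheme: str
    seed: int
    r_undefined: bool = False


def _holdout_split(
    df: pd.DataFrame, scheme: str, seed: int, test_fraction: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    if scheme == "by-location":
        units = np.sort(df["location_id"].unique())
    elif scheme == "by-year":
        units = np.sort(df["year"].unique())
    elif scheme == "random":
        n_test = max(1, int(round(test_fraction * len(df))))
        idx = rng.permutation(len(df))
        test_mask = np.zeros(len(df), dtype=bool)
        test_mask[idx[:n_test]] = True
        return df.loc[~test_mask], df.loc[test_mask]
    else:
        raise DomainError(f"holdout scheme must be one of {HOLDOUT_SCHEMES}, got {scheme!r}")
    n_test = max(1, int(round(test_fraction * len(units))))
    held = set(rng.choice(units, size=n_test, replace=False).tolist())
    col = "location_id" if scheme == "by-location" else "year"
    mask = df[col].isin(held)
    return df.loc[~mask], df.loc[mask]


def evaluate_out_of_sample(
    regressor: IntakeRegressor | str,
    df: pd.DataFrame,
    scheme: str = "by-location",
    seed: int = 0,
    test_fraction: float = 0.2,
) -> OOSMetrics:
    """Out-of-sample RMSE and Pearson correlation for one regressor.

    Splits the matched intake/availability rows by the chosen scheme, fits
    on the training fold, and scores on the held-out fold.  Deterministic
    given ``(scheme, seed)``.  A constant prediction vector leaves the
    correlation undefined: ``r`` is NaN, ``r_undefined`` is set, and the
    RMSE then equals the held-out outcome spread around the constant.
    """
    if isinstance(regressor, str):
        regressor = make_regressor(regressor, seed=seed)
    train, test = _holdout_split(df, scheme, seed, test_fraction)
    if test.empty:
        raise SchemaError("holdout fold is empty")
    if train.empty:
        raise SchemaError("training fold is empty")
    regressor.fit(train)
    pred = regressor.predict(test)
    y = (test["intake"] if "intake" in test.columns else test["mean_intake"]).to_numpy(
        dtype=float
    )
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    if np.std(pred) == 0 or np.std(y) == 0:
        return OOSMetrics(rmse, float("nan"), len(train), len(test), scheme, seed, True)
    r = float(np.corrcoef(pred, y)[0, 1])
    return OOSMetrics(rmse, r, len(train), len(test), scheme, seed, False)


# --- energy-share validation ------------------------------------------------


def compare_energy_shares(
    availability_panel: pd.DataFrame,
    intake: pd.DataFrame,
    macros: Sequence[str] = SHARE_MACROS,
) -> pd.DataFrame:
    """Macronutrient energy-share differences between availability and surveys.

    Both sources are reduced to the percentage of energy from each
    macronutrient (denominator = sum of the compared macronutrient energies),
    per location-year; survey intake is first averaged over age/sex groups.
    Because shares are ratios, any uniform waste factor between availability
    and intake cancels, so nonzero differences reflect compositional
    disagreement, not waste.

    Returns a long table ``location_id, year, macronutrient,
    share_availability, share_intake, abs_diff`` (percentage points), for
    the location-years present in both sources.  Cells with zero total
    energy in either source are skipped with a warning.
    """
    ids = [f"{m}_kcal" for m in macros]

    avail = availability_panel[availability_panel["nutrient_id"].isin(ids)]
    avail_wide = avail.pivot_table(index=["location_id", "year"], columns="nutrient_id",
                                   values="value", aggfunc="first")
    if missing := set(ids) - set(avail_wide.columns):
        raise SchemaError(f"availability panel lacks {sorted(missing)}")

    intake_sub = intake[intake["nutrient_id"].isin(ids)]
    if intake_sub.empty:
        raise SchemaError(f"intake table has no rows for macronutrient energies {ids}")
    intake_nat = (
        intake_sub.groupby(["location_id", "year", "nutrient_id"])["mean_intake"]
        .mean()
        .unstack("nutrient_id")
    )
    if missing := set(ids) - set(intake_nat.columns):
        raise SchemaError(f"intake table lacks {sorted(missing)}")

    joined = avail_wide[ids].join(intake_nat[ids], how="inner",
                                  lsuffix="_avail", rsuffix="_intake")
    if joined.empty:
        raise SchemaError("availability and intake share no location-years")
    tot_a = joined[[f"{i}_avail" for i in ids]].sum(axis=1)
    tot_i = joined[[f"{i}_intake" for i in ids]].sum(axis=1)
    bad = (tot_a <= 0) | (tot_i <= 0)
    if bad.any():
        logger.warning("skipping %d location-years with zero total energy", int(bad.sum()))
        joined, tot_a, tot_i = joined[~bad], tot_a[~bad], tot_i[~bad]

    frames = []
    for macro, nid in zip(macros, ids):
        share_a = joined[f"{nid}_avail"] / tot_a * 100.0
        share_i = joined[f"{nid}_intake"] / tot_i * 100.0
        frames.append(
            pd.DataFrame(
                {
                    "macronutrient": macro,
                    "share_availability": share_a,
                    "share_intake": share_i,
                    "abs_diff": (share_a - share_i).abs(),
                }
            ).reset_index()
        )
    return pd.concat(frames, ignore_index=True)[
        ["location_id", "year", "macronutrient", "share_availability", "share_intake", "abs_diff"]
    ]
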