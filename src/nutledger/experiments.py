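"""Simulation studies that quantify recovery of known synthetic-world truth.

These are the package's standing calibration experiments: generate a world
with known ground truth, run a pipeline stage, and measure how well the
truth is recovered.  They back both the test suite and the reproduction
script, and are sized to run on a single CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .availability import aggregate_availability
from .intake import fit_intake_model
from .stgpr import STGPRParams, fill_time_series, stage1_prior
from .synthetic_world import (
    WorldConfig,
    generate_composition_table,
    generate_survey_intake,
    generate_world,
)


@dataclass
class StgprRecoveryResult:
    """Held-out recovery of one gap-filling run against ground truth."""

    seed: int
    rmse_stage1: float
    rmse_stage3: float
    coverage: float  # fraction of held-out truth inside the 95% interval
    n_held_out: int


def stgpr_recovery_experiment(
    seeds,
    n_locations: int = 150,
    year_start: int = 1980,
    year_end: int = 2013,
    missing_fraction: float = 0.2,
    n_items: int = 100,
    nutrient: str = "energy_kcal",
    n_draws: int = 1000,
) -> list[StgprRecoveryResult]:
    """Gap-fill masked synthetic panels and score held-out cells.

    For each seed: generate a world, mask ``missing_fraction`` of
    location-years, run the three-stage smoother on the observed cells, and
    compare held-out cells against the complete ground-truth panel — both
    the posterior mean (RMSE, against the stage-1 prior as baseline) and the
    95% interval (empirical coverage).
    """
    results = []
    for seed in seeds:
        cfg = WorldConfig(
            n_items=n_items, n_locations=n_locations, year_start=year_start,
            year_end=year_end, missing_fraction=missing_fraction, seed=seed,
        )
        world = generate_world(cfg, intake_nutrients=["energy_kcal"])
        panel = aggregate_availability(world.supply, world.composition, world.matching)
        params = STGPRParams(seed=seed, n_draws=n_draws)
        filled = fill_time_series(panel, world.covariates, params, nutrients=[nutrient])

        truth = world.ground_truth.true_availability_panel
        truth = truth[truth["nutrient_id"] == nutrient]
        merged = filled.merge(
            truth[["location_id", "year", "value"]],
            on=["location_id", "year"],
            suffixes=("", "_true"),
        )
        held = merged[~merged["observed"]]

        observed = panel[panel["nutrient_id"] == nutrient]
        prior1, _ = stage1_prior(
            observed[["location_id", "year", "value"]], world.covariates
        )
        held_prior = held[["location_id", "year", "value_true"]].merge(
            prior1, on=["location_id", "year"]
        )

        rmse3 = float(np.sqrt(np.mean((held["value"] - held["value_true"]) ** 2)))
        rmse1 = float(
            np.sqrt(np.mean((held_prior["prior"] - held_prior["value_true"]) ** 2))
        )
        coverage = float(
            np.mean((held["value_true"] >= held["lower"]) & (held["value_true"] <= held["upper"]))
        )
        results.append(
            StgprRecoveryResult(seed, rmse1, rmse3, coverage, len(held))
        )
    return results


@dataclass
class BetaRecoveryResult:
    """Slope recovery of the intake regression over seeded replicates."""

    ci_coverage: float  # fraction of replicates whose 95% CI covers the truth
    mean_bias_fraction: float  # mean (beta_hat - beta_true) / beta_true
    true_beta: float
    n_replicates: int
    n_rows: int


def beta_recovery_experiment(
    n_replicates: int = 50,
    n_rows: int = 5000,
    base_seed: int = 0,
    n_locations: int = 60,
    year_start: int = 1990,
    year_end: int = 2013,
) -> BetaRecoveryResult:
    """Refit the intake model on freshly simulated surveys and score the slope.

    One availability world is generated once; each replicate redraws the
    survey-intake table (new age/sex/region effects and noise), subsamples
    ``n_rows`` matched rows, fits the mixed-effects intake model, and checks
    whether the 95% CI for the availability slope covers the generator's
    true slope ``beta * (1 - waste_factor)``.
    """
    base_cfg = WorldConfig(
        n_items=60, n_locations=n_locations, year_start=year_start, year_end=year_end,
        missing_fraction=0.0, seed=base_seed,
    )
    base_world = generate_world(base_cfg, intake_nutrients=["energy_kcal"])
    truth = base_world.ground_truth
    avail = truth.true_availability_panel.query("nutrient_id == 'energy_kcal'")
    super_regions = truth.super_regions

    covered = []
    biases = []
    true_beta = None
    for rep in range(n_replicates):
        cfg = WorldConfig(
            n_items=base_cfg.n_items, n_locations=n_locations, year_start=year_start,
            year_end=year_end, missing_fraction=0.0, seed=base_seed + 1 + rep,
        )
        intake, rep_truth = generate_survey_intake(
            cfg, avail, nutrients=["energy_kcal"], super_regions=super_regions
        )
        true_beta = rep_truth.true_beta
        matched = (
            intake.merge(
                avail[["location_id", "year", "value"]].rename(
                    columns={"value": "availability"}
                ),
                on=["location_id", "year"],
            )
            .rename(columns={"mean_intake": "intake"})
        )
        matched["super_region"] = matched["location_id"].map(super_regions)
        rng = np.random.default_rng(base_seed + 1 + rep)
        sample = matched.iloc[rng.choice(len(matched), size=n_rows, replace=False)]
        fit = fit_intake_model(sample)
        lo, hi = fit.beta_ci
        covered.append(lo <= true_beta <= hi)
        biases.append((fit.beta - true_beta) / true_beta)
    return BetaRecoveryResult(
        ci_coverage=float(np.mean(covered)),
        mean_bias_fraction=float(np.mean(biases)),
        true_beta=float(true_beta),
        n_replicates=n_replicates,
        n_rows=n_rows,
    )


def atwater_roundtrip_error(n_items: int = 1000, seed: int = 0) -> float:
    """Max |forward carbohydrate - carbohydrate by difference| over generated items."""
    from .composition import carbohydrate_by_difference_table

    cfg = WorldConfig(n_items=n_items, n_locations=10, year_start=2000, year_end=2001,
                      seed=seed)
    table, truth = generate_composition_table(cfg)
    recovered = carbohydrate_by_difference_table(table)
    forward = truth.true_item_compositions["carbohydrate_g"]
    return float(np.max(np.abs(recovered.to_numpy() - forward.to_numpy())))


def share_closure_deviation(world=None, seed: int = 0) -> float:
    """Max |carb+protein+fat+alcohol share - 100| (points) over all synthetic cells."""
    from .availability import energy_shares_table

    if world is None:
        cfg = WorldConfig(n_items=50, n_locations=30, year_start=1980, year_end=2013,
                          seed=seed)
        world = generate_world(cfg, intake_nutrients=["energy_kcal"])
    shares = energy_shares_table(world.ground_truth.true_availability_panel)
    total = shares[["carbohydrate", "protein", "fat", "alcohol"]].sum(axis=1)
    return float(np.max(np.abs(total - 100.0)))
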