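"""End-to-end pipeline runner: generate -> compute -> smooth -> sdi -> report -> validate.

The runner reads a single YAML (or dict) configuration, executes every stage
in order, and writes a manifest with SHA-256 checksums of all inputs and
outputs so that reruns can be compared bit-for-bit.  Any stage failure aborts
with the stage name attached to the error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .availability import aggregate_availability, energy_shares_table
from .errors import ConfigurationError, NutledgerError
from .intake import compare_energy_shares, evaluate_out_of_sample
from .reporting import round_kcal, round_share
from .sdi import aggregate_by_level, assign_quintiles, sdi_from_covariates
from .stgpr import STGPRParams, fill_time_series
from .synthetic_world import WorldConfig, generate_world, write_world
from .trends import availability_correlations, share_correlation_matrix, trend_report

logger = logging.getLogger(__name__)

INPUT_KEYS = ("supply", "composition", "matching", "covariates", "intake")


@dataclass
class PipelineConfig:
    """Paths and knobs for one pipeline run.  ``seed`` is mandatory."""

    out_dir: str
    seed: int
    supply: str | None = None
    composition: str | None = None
    matching: str | None = None
    covariates: str | None = None
    intake: str | None = None
    generate: dict | None = None  # WorldConfig fields; when set, inputs are generated
    stgpr: dict = field(default_factory=dict)  # STGPRParams overrides
    nutrients: list | None = None  # nutrients to gap-fill; None = all
    reference_year: int | None = None  # quintile membership year; None = final year
    year_start: int | None = None
    year_end: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"pipeline config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "seed" not in raw or "out_dir" not in raw:
            raise ConfigurationError("pipeline config requires `seed` and `out_dir`")
        return cls(**raw)


class StageError(NutledgerError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage
        self.cause = err


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    Stages: optional synthetic-world generation, availability accounting,
    ST-GPR gap-filling, SDI/quintiles, trend and correlation reporting, and
    (when an intake table is present) the availability-vs-survey validation.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    inputs: dict[str, Path] = {}
    if config.generate is not None:
        stage = "generate"
        try:
            world_cfg = WorldConfig(**{**config.generate, "seed": config.seed})
            world = generate_world(world_cfg)
            gen_dir = out / "inputs"
            write_world(world, gen_dir)
            for key, name in zip(INPUT_KEYS, ("supply", "composition", "matching",
                                              "covariates", "intake")):
                inputs[key] = gen_dir / f"{name}.csv"
        except Exception as err:
            raise StageError(stage, err) from err
    else:
        for key in INPUT_KEYS:
            path = getattr(config, key)
            if path is None:
                if key == "intake":
                    continue  # validation stage is optional
                raise ConfigurationError(f"pipeline config missing input path: {key}")
            p = Path(path)
            if not p.exists():
                raise ConfigurationError(f"input file does not exist: {p}")
            inputs[key] = p

    try:
        stage = "compute"
        supply = pd.read_csv(inputs["supply"])
        composition = pd.read_csv(inputs["composition"])
        matching = pd.read_csv(inputs["matching"])
        covariates = pd.read_csv(inputs["covariates"])
        panel = aggregate_availability(supply, composition, matching)
        panel.to_csv(out / "availability.csv", index=False)

        stage = "smooth"
        params = STGPRParams(**{**config.stgpr, "seed": config.seed})
        filled = fill_time_series(panel, covariates, params, nutrients=config.nutrients)
        filled.to_csv(out / "filled.csv", index=False)

        stage = "sdi"
        sdi = sdi_from_covariates(covariates)
        ref_year = config.reference_year or int(sdi["year"].max())
        at_ref = sdi[sdi["year"] == ref_year].set_index("location_id")["sdi"]
        levels = assign_quintiles(at_ref)
        sdi_out = sdi.copy()
        sdi_out["level"] = sdi_out["location_id"].map(levels)
        sdi_out.to_csv(out / "sdi.csv", index=False)

        stage = "report"
        population = covariates[["location_id", "year", "population"]]
        aggregated = aggregate_by_level(filled, levels, population)
        aggregated.to_csv(out / "aggregated.csv", index=False)
        y0 = config.year_start or int(filled["year"].min())
        y1 = config.year_end or int(filled["year"].max())
        trends = trend_report(aggregated, y0, y1)
        trends.to_csv(out / "trends.csv", index=False)
        shares = energy_shares_table(filled)
        shares_last = shares[shares["year"] == y1].drop(columns="year")
        corr = share_correlation_matrix(shares_last)
        corr.r.to_csv(out / "correlations.csv")
        corr.p.to_csv(out / "correlation_pvalues.csv")

        if "intake" in inputs:
            stage = "validate"
            intake = pd.read_csv(inputs["intake"])
            diff = compare_energy_shares(filled, intake)
            diff.to_csv(out / "share_validation.csv", index=False)
            matched = intake.merge(
                filled[filled["nutrient_id"] == "energy_kcal"][
                    ["location_id", "year", "value"]
                ].rename(columns={"value": "availability"}),
                on=["location_id", "year"],
            ).merge(
                covariates[["location_id", "year", "super_region"]],
                on=["location_id", "year"],
            )
            matched = matched[matched["nutrient_id"] == "energy_kcal"].rename(
                columns={"mean_intake": "intake"}
            )
            metrics = evaluate_out_of_sample("linear", matched, seed=config.seed)
            (out / "metrics.json").write_text(
                json.dumps(
                    {"rmse": metrics.rmse, "r": metrics.r, "scheme": metrics.scheme,
                     "n_train": metrics.n_train, "n_test": metrics.n_test},
                    indent=2,
                )
            )
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, err) from err

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in vars(config).items()},
        "inputs": {k: _sha256(p) for k, p in inputs.items()},
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.csv")) if p.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def summarise(artifact_dir) -> dict:
    """Human-readable summary of a pipeline artifact directory.

    Reports per-scope energy availability (kcal, rounded to the nearest 5)
    and macronutrient shares (one decimal) at the final year, plus the
    largest net changes — recomputed from the written outputs, not cached.
    """
    out = Path(artifact_dir)
    agg_path = out / "aggregated.csv"
    if not agg_path.exists():
        raise ConfigurationError(f"no pipeline outputs found in {out}")
    aggregated = pd.read_csv(agg_path)
    year = int(aggregated["year"].max())
    final = aggregated[aggregated["year"] == year]

    summary: dict = {"year": year, "scopes": {}}
    for scope, grp in final.groupby("scope"):
        values = grp.set_index("nutrient_id")["value"]
        if "energy_kcal" not in values.index or values["energy_kcal"] <= 0:
            continue
        energy = float(values["energy_kcal"])
        shares = {
            nid[: -len("_kcal")]: round_share(v / energy * 100.0)
            for nid, v in values.items()
            if nid.endswith("_kcal") and nid != "energy_kcal"
        }
        summary["scopes"][scope] = {"energy_kcal": round_kcal(energy), "shares_pct": shares}

    trends_path = out / "trends.csv"
    if trends_path.exists():
        trends = pd.read_csv(trends_path)
        energy_trends = trends[trends["nutrient_id"] == "energy_kcal"]
        summary["energy_net_change_kcal"] = {
            row["scope"]: round_kcal(row["net_change"]) for _, row in energy_trends.iterrows()
        }
    return summary


def format_summary(summary: dict) -> str:
    lines = [f"Final-year ({summary['year']}) availability by scope:"]
    for scope, info in summary["scopes"].items():
        shares = ", ".join(
            f"{m} {s:.1f}%" for m, s in sorted(info["shares_pct"].items())
            if m in ("carbohydrate", "protein", "fat", "alcohol")
        )
        lines.append(f"  {scope}: {info['energy_kcal']:.0f} kcal/person/day ({shares})")
    if "energy_net_change_kcal" in summary:
        lines.append("Net change in energy availability over the study period:")
        for scope, change in summary["energy_net_change_kcal"].items():
            lines.append(f"  {scope}: {change:+.0f} kcal/person/day")
    return "\n".join(lines)
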