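"""End-to-end orchestration: stages, file schemas, validation, manifest.

The pipeline runs, in order: simulate (optional) -> classify -> index ->
sol-fit -> adjust-poverty -> gs-summarize. Every stage reads and writes
headed CSV files in one output directory, so any stage can also start from
externally supplied files with the same schemas. A JSON manifest records
the config snapshot, seed, input digests and outputs; re-running with an
identical manifest reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assets import index_from_frame
from .config import SimConfig
from .domains import DOMAINS, WG_COLUMNS
from .gs import CostAggregator, affordability_percentile, wage_gap
from .poverty import MultiplierPolicy, PovertyAdjuster
from .sol import MultiplierTable, SolExtraCostEstimator, assign_quintiles, normalize_expenditure
from .simulate import generate_population
from .wg import WashingtonGroupClassifier

log = logging.getLogger("discost")

STAGES = ("simulate", "classify", "index", "sol-fit", "adjust-poverty", "gs-summarize")


class PipelineDependencyError(FileNotFoundError):
    """A stage's required input file is missing."""


class ConfigurationError(ValueError):
    """The run configuration is invalid."""


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    version: str
    seed: int | None
    config: dict
    stages: list = field(default_factory=list)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _need(out_dir: Path, name: str, stage: str) -> Path:
    p = out_dir / name
    if not p.exists():
        raise PipelineDependencyError(
            f"stage {stage!r} requires {p}; run the producing stage first or supply the file"
        )
    return p


def load_run_config(source) -> dict:
    """Load a structured run config (YAML path or dict) with per-module sections."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(source or {})
    for key in cfg:
        if key not in ("simulate", "sol", "poverty", "gs"):
            raise ConfigurationError(f"unknown config section {key!r}")
    return cfg


def validate_inputs(files: dict) -> pd.DataFrame:
    """Column-level validation of input CSVs.

    ``files`` maps table name ("households", "members", "cost_items") to a
    path. Returns a violation table (file, row, column, problem); empty
    means clean. Checks column presence, WG codes 0-3, binary asset
    indicators, positive expenditures and poverty lines, and
    household<->member referential integrity.
    """
    rows = []

    def add(fname, row, column, problem):
        rows.append({"file": str(fname), "row": row, "column": column, "problem": problem})

    tables = {}
    for name, path in files.items():
        try:
            tables[name] = pd.read_csv(path)
        except Exception as exc:  # unreadable file is itself a violation
            add(path, -1, "", f"unreadable: {exc}")
    hh = tables.get("households")
    if hh is not None:
        fname = files["households"]
        for col in ("household_id", "exp_pc", "poverty_line"):
            if col not in hh.columns:
                add(fname, -1, col, "missing required column")
        for col in ("exp_pc", "poverty_line"):
            if col in hh.columns:
                for i in hh.index[~(hh[col] > 0)]:
                    add(fname, int(i), col, "must be positive")
        for col in [c for c in hh.columns if c.startswith(("asset_", "dwell_")) and c != "asset_index"]:
            bad = ~hh[col].isin([0, 1])
            for i in hh.index[bad]:
                add(fname, int(i), col, "asset/dwelling indicators must be 0/1")
        if "household_id" in hh.columns and hh["household_id"].duplicated().any():
            for i in hh.index[hh["household_id"].duplicated()]:
                add(fname, int(i), "household_id", "duplicate household id")
    mem = tables.get("members")
    if mem is not None:
        fname = files["members"]
        for col in ("household_id", *WG_COLUMNS):
            if col not in mem.columns:
                add(fname, -1, col, "missing required column")
        for col in WG_COLUMNS:
            if col in mem.columns:
                bad = ~mem[col].isin([0, 1, 2, 3])
                for i in mem.index[bad]:
                    add(fname, int(i), col, f"WG code out of range: {mem.loc[i, col]!r}")
        if hh is not None and "household_id" in mem.columns and "household_id" in hh.columns:
            known = set(hh["household_id"])
            orphan = ~mem["household_id"].isin(known)
            for i in mem.index[orphan]:
                add(fname, int(i), "household_id", "member references unknown household")
            seen = set(mem["household_id"])
            for i in hh.index[~hh["household_id"].isin(seen)]:
                add(files["households"], int(i), "household_id", "household has no members")
    items = tables.get("cost_items")
    if items is not None:
        from .domains import GS_CATEGORIES

        fname = files["cost_items"]
        if "category" in items.columns:
            bad = ~items["category"].isin(GS_CATEGORIES)
            for i in items.index[bad]:
                add(fname, int(i), "category", f"unknown category {items.loc[i, 'category']!r}")
        for col in ("purchase_price", "lifespan_months", "recurring_cost", "frequency_per_month"):
            if col in items.columns:
                for i in items.index[items[col] < 0]:
                    add(fname, int(i), col, "must be non-negative")
    return pd.DataFrame(rows, columns=["file", "row", "column", "problem"])


def run_pipeline(config, stages=None, out_dir=".", seed: int | None = None) -> RunManifest:
    """Execute the requested stages in canonical order and write a manifest.

    ``config`` is a YAML path or dict with optional sections ``simulate``,
    ``sol``, ``poverty``, ``gs``. ``seed`` overrides the simulate section's
    seed. Raises :class:`PipelineDependencyError` when a stage's upstream
    file is absent and :class:`ConfigurationError` on bad configuration.
    """
    cfg = load_run_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    if not stages:
        raise ConfigurationError("no recognized stages requested")
    manifest = RunManifest(version=__version__, seed=seed, config=cfg)
    sol_cfg = cfg.get("sol", {}) or {}
    pov_cfg = cfg.get("poverty", {}) or {}
    gs_cfg = cfg.get("gs", {}) or {}

    def emit(name: str, df: pd.DataFrame):
        p = out / name
        df.to_csv(p, index=False)
        manifest.outputs[str(p)] = _digest(p)
        return p

    def consume(name: str, stage: str) -> pd.DataFrame:
        p = _need(out, name, stage)
        manifest.inputs.setdefault(str(p), _digest(p))
        return pd.read_csv(p)

    for stage in stages:
        log.info("stage %s", stage)
        if stage == "simulate":
            sim = dict(cfg.get("simulate", {}) or {})
            if seed is not None:
                sim["seed"] = seed
            try:
                sim_cfg = SimConfig.from_dict(sim)
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(str(exc)) from exc
            survey = generate_population(sim_cfg)
            for name, df in (
                ("households.csv", survey.households),
                ("members.csv", survey.members),
                ("respondents.csv", survey.respondents),
                ("cost_items.csv", survey.cost_items),
                ("truth.csv", survey.truth.df),
            ):
                emit(name, df)
            log.info("simulated %d households, seed=%s", len(survey.households), sim_cfg.seed)
        elif stage == "classify":
            members = consume("members.csv", stage)
            households = consume("households.csv", stage)
            flags = WashingtonGroupClassifier().household_flags(members)
            emit("households_classified.csv", households.merge(flags, on="household_id", how="left"))
        elif stage == "index":
            hh = consume("households_classified.csv", stage)
            if "sol_index" not in hh.columns:
                hh["sol_index"] = index_from_frame(hh)
            emit("households_indexed.csv", hh)
        elif stage == "sol-fit":
            hh = consume("households_indexed.csv", stage)
            est = SolExtraCostEstimator(
                thresholds=tuple(sol_cfg.get("thresholds", ("lower", "higher"))),
                controls=tuple(sol_cfg.get("controls", ("hh_size", "urban", "head_age", "head_sex", "head_edu"))),
                alpha_level=float(sol_cfg.get("alpha_level", 0.10)),
                expenditure_mode=sol_cfg.get("expenditure_mode", "levels"),
                exclusive_strata=bool(sol_cfg.get("exclusive_strata", True)),
                include_bottom40=bool(sol_cfg.get("include_bottom40", True)),
                weight_col=sol_cfg.get("weight_col"),
            ).fit(hh)
            table = est.multiplier_table_
            emit("multiplier_table.csv", table.df)
            dump = pd.DataFrame(
                [
                    {
                        "type": f.domain,
                        "quintile": MultiplierTable.quintile_label(f.quintile),
                        "threshold": f.threshold,
                        "alpha_hat": f.alpha_hat,
                        "beta_hat": f.beta_hat,
                        "se_beta": f.se_beta,
                        "intercept": f.intercept,
                        "p_beta": f.p_beta,
                        "n_obs": f.n_obs,
                        "n_disabled": f.n_disabled,
                        "mean_y": f.mean_y,
                    }
                    for f in est.fits_.values()
                ]
            )
            emit("stratum_fits.csv", dump)
            log.info(
                "sol-fit: %d strata, %d blanked, mode=%s",
                len(table.df),
                table.n_blank,
                sol_cfg.get("expenditure_mode", "levels"),
            )
        elif stage == "adjust-poverty":
            hh = consume("households_indexed.csv", stage)
            table = MultiplierTable.read_csv(_need(out, "multiplier_table.csv", stage))
            try:
                policy = MultiplierPolicy(
                    source=pov_cfg.get("source", "bottom40_pooled"),
                    multiple_rule=pov_cfg.get("multiple_rule", "max_over_types"),
                    blank_rule=pov_cfg.get("blank_rule", "treat_as_zero"),
                )
            except ValueError as exc:
                raise ConfigurationError(str(exc)) from exc
            hh["y"] = normalize_expenditure(hh["exp_pc"], hh["poverty_line"])
            hh["quintile"] = assign_quintiles(hh["y"].to_numpy())
            adj = PovertyAdjuster(policy=policy, threshold=pov_cfg.get("threshold", "higher"))
            adj.fit(table)
            adjusted = adj.transform(hh)
            emit("households_adjusted.csv", adjusted)
            emit("poverty_rates.csv", adj.headcount(adjusted))
            log.info("adjust-poverty: policy=%s blank_rule=%s", policy.source, policy.blank_rule)
        elif stage == "gs-summarize":
            items = consume("cost_items.csv", stage)
            respondents = consume("respondents.csv", stage)
            agg = CostAggregator(amortization=gs_cfg.get("amortization", "straight_line"))
            agg.fit(items, respondents[["respondent_id", "disability_type", "age_band"]])
            summary = agg.summarize()
            emit("cost_summaries.csv", summary)
            emit("cost_summaries_by_age.csv", agg.summarize(age_band_col="age_band"))
            wage = gs_cfg.get("minimum_wage")
            if wage:
                emit("wage_gaps.csv", wage_gap(summary, float(wage)))
            hh_path = out / "households.csv"
            if hh_path.exists():
                hh = pd.read_csv(hh_path)
                med = float(
                    summary.loc[summary["disability_type"] == "overall", "median"].iloc[0]
                )
                pct = affordability_percentile(med, hh["exp_pc"].to_numpy(), hh.get("weight"))
                emit(
                    "affordability.csv",
                    pd.DataFrame(
                        [{"overall_median_cost": med, "expenditure_percentile": pct}]
                    ),
                )
        manifest.stages.append(stage)
    manifest.write(out / "manifest.json")
    return manifest
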