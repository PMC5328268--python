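"""End-to-end orchestration: filter -> rarefy -> overlap -> summarize -> infer.

``run_pipeline`` executes every stage of the analysis on either a measured
dataset (trait CSV + metadata CSV) or a named synthetic preset, writes all
result tables as CSV, and records a machine-readable manifest (config echo,
seed, per-stage record counts) from which every output is re-derivable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import synthetic
from .data_model import (
    Dataset,
    count_summary,
    filter_min_individuals,
    read_metadata,
    read_trait_table,
)
from .errors import ConfigError, InsufficientDataError, ItvOverlapError, UndefinedTestError
from .inference import compare_methods, fit_itv_model, regress_summary
from .overlap import (
    GRID_POINTS,
    HIGH_THRESHOLD,
    LOW_THRESHOLD,
    dataset_overlap,
    summaries_table,
    summarize_overlap,
)
from .rarefaction import DEFAULT_N_DRAW, DEFAULT_N_REPS, rarefy_dataset

log = logging.getLogger("itvoverlap")

STAGES = ("load", "filter", "rarefy", "overlap", "summarize", "inference")
SUMMARY_RESPONSES = ("median_overlap", "prop_low", "prop_high")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    trait_table: str | None = None
    meta_table: str | None = None
    preset: str | None = None
    traits: tuple[str, ...] = ("leaf_size", "sla")
    min_individuals: int = 5
    n_draw: int = DEFAULT_N_DRAW
    n_reps: int = DEFAULT_N_REPS
    seed: int = 0
    aggregation: str = "per_replicate"
    methods: tuple[str, ...] = ("normal", "kernel")
    bandwidth_rule: str = "nrd0"
    grid_points: int = GRID_POINTS
    low_threshold: float = LOW_THRESHOLD
    high_threshold: float = HIGH_THRESHOLD
    family_config: str = "log_gaussian"
    transform: str = "sqrt"
    outdir: str | None = None
    verbose: bool = False

    def __post_init__(self) -> None:
        if not self.low_threshold < self.high_threshold:
            raise ConfigError("thresholds must satisfy low < high")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        if self.trait_table is None and self.preset is None:
            raise ConfigError("either trait_table (+ meta_table) or preset is required")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("traits", "methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    rarefied: dict  # trait -> DataFrame
    matrices: dict  # (trait, method) -> list[OverlapMatrix]
    summaries: pd.DataFrame
    regressions: pd.DataFrame
    itv_fits: dict  # trait -> ItvModelFit
    comparisons: pd.DataFrame
    manifest: dict
    dataset: Dataset = field(repr=False, default=None)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ItvOverlapError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc

        return wrapper

    return deco


def load_inputs(cfg: PipelineConfig) -> Dataset:
    """Load measured data or generate the configured synthetic preset."""
    if cfg.trait_table is not None:
        ds = read_trait_table(cfg.trait_table)
        if cfg.meta_table is None:
            raise ConfigError("meta_table is required with trait_table")
        meta = read_metadata(cfg.meta_table)
        return Dataset(records=ds.records, meta=meta, load_report=ds.load_report)
    scen = synthetic.get_preset(cfg.preset)
    scen.seed = cfg.seed
    return synthetic.generate_gradient(scen)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all stages and (optionally) write results under ``cfg.outdir``."""
    if cfg.verbose:
        logging.basicConfig(level=logging.INFO)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "seed": cfg.seed,
        "stages_completed": [],
        "counts": {},
    }

    ds = _stage("load")(load_inputs)(cfg)
    manifest["counts"]["load"] = count_summary(ds)
    if ds.load_report is not None:
        manifest["counts"]["load"]["n_dropped"] = ds.load_report.n_dropped
    manifest["stages_completed"].append("load")
    log.info("loaded %s records", len(ds.records))

    filtered = {}
    for trait in cfg.traits:
        filtered[trait] = _stage("filter")(filter_min_individuals)(
            ds, trait, k=cfg.min_individuals
        )
    manifest["counts"]["filter"] = {
        t: count_summary(filtered[t])["n_species_groups"] for t in cfg.traits
    }
    manifest["stages_completed"].append("filter")

    rarefied = {}
    for trait in cfg.traits:
        rarefied[trait] = _stage("rarefy")(rarefy_dataset)(
            filtered[trait],
            trait,
            n_draw=cfg.n_draw,
            n_reps=cfg.n_reps,
            seed=cfg.seed,
            aggregation=cfg.aggregation,
        )
    manifest["counts"]["rarefy"] = {t: len(rarefied[t]) for t in cfg.traits}
    manifest["stages_completed"].append("rarefy")

    matrices = {}
    skipped: dict = {}
    for trait in cfg.traits:
        for method in cfg.methods:
            kwargs = (
                {"rarefied": rarefied[trait]}
                if method == "normal"
                else {"bandwidth_rule": cfg.bandwidth_rule, "grid_points": cfg.grid_points}
            )
            mats, skip = _stage("overlap")(dataset_overlap)(
                filtered[trait], trait, method=method, **kwargs
            )
            matrices[(trait, method)] = mats
            skipped[f"{trait}/{method}"] = skip
    manifest["counts"]["overlap"] = {
        f"{t}/{m}": sum(len(mat.pairs) for mat in mats)
        for (t, m), mats in matrices.items()
    }
    manifest["skipped_forests"] = skipped
    manifest["stages_completed"].append("overlap")

    all_sums = []
    for (trait, method), mats in matrices.items():
        for mat in mats:
            all_sums.append(
                summarize_overlap(mat, low=cfg.low_threshold, high=cfg.high_threshold)
            )
    summaries = summaries_table(all_sums)
    manifest["counts"]["summarize"] = len(summaries)
    manifest["stages_completed"].append("summarize")

    reg_rows = []
    itv_fits = {}
    comp_rows = []
    if ds.meta is not None:
        for trait in cfg.traits:
            for method in cfg.methods:
                sub = summaries[
                    (summaries["trait"] == trait) & (summaries["method"] == method)
                ]
                for response in SUMMARY_RESPONSES:
                    try:
                        fit = _stage("inference")(regress_summary)(
                            sub, ds.meta, response=response, transform=cfg.transform
                        )
                    except InsufficientDataError:
                        continue
                    reg_rows.append(dataclasses.asdict(fit))
            try:
                itv_fits[trait] = _stage("inference")(fit_itv_model)(
                    rarefied[trait], ds.meta, family_config=cfg.family_config, trait=trait
                )
            except InsufficientDataError as exc:
                log.warning("ITV model skipped for %s: %s", trait, exc)
            if {"normal", "kernel"} <= set(cfg.methods):
                sub = summaries[summaries["trait"] == trait]
                med = sub.pivot(index="forest_id", columns="method", values="median_overlap")
                try:
                    comp = _stage("inference")(compare_methods)(
                        med["normal"], med["kernel"]
                    )
                    comp_rows.append(
                        {
                            "trait": trait,
                            "n": comp.n,
                            "z": comp.z,
                            "abs_z": comp.abs_z,
                            "p_value": comp.p_value,
                        }
                    )
                except (InsufficientDataError, UndefinedTestError) as exc:
                    log.warning("method comparison skipped for %s: %s", trait, exc)
    regressions = pd.DataFrame(reg_rows)
    comparisons = pd.DataFrame(comp_rows)
    manifest["stages_completed"].append("inference")

    result = PipelineResult(
        rarefied=rarefied,
        matrices=matrices,
        summaries=summaries,
        regressions=regressions,
        itv_fits=itv_fits,
        comparisons=comparisons,
        manifest=manifest,
        dataset=ds,
    )
    if cfg.outdir is not None:
        write_results(result, cfg)
    return result


def itv_fit_table(itv_fits: dict) -> pd.DataFrame:
    """Mixed-model coefficient table (one row per trait and term)."""
    rows = []
    for trait, fit in itv_fits.items():
        for _, row in fit.coefficients.iterrows():
            rows.append(
                {
                    "trait": trait,
                    "n_obs": fit.n_obs,
                    "term": row["term"],
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "t": row["t"],
                    "p": row["p"],
                    "r2_marginal": fit.r2_marginal,
                    "r2_conditional": fit.r2_conditional,
                    "fixed_effects_only": fit.fixed_effects_only,
                }
            )
    return pd.DataFrame(rows)


def write_results(result: PipelineResult, cfg: PipelineConfig) -> Path:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for trait, df in result.rarefied.items():
        df.to_csv(outdir / f"rarefied_{trait}.csv", index=False)
    result.summaries.to_csv(outdir / "overlap_summaries.csv", index=False)
    if len(result.regressions):
        result.regressions.to_csv(outdir / "summary_regressions.csv", index=False)
    if result.itv_fits:
        itv_fit_table(result.itv_fits).to_csv(outdir / "itv_model.csv", index=False)
    if len(result.comparisons):
        result.comparisons.to_csv(outdir / "method_comparison.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    return outdir
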