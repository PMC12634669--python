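"""End-to-end orchestration: simulate → backcast → AGB → features → train → map.

A run is driven by a :class:`RunConfig` (YAML-loadable), executes the
requested stages into one output directory, and logs one JSON line per
stage with timings and the cleaning/fallback tallies that matter for
auditing. Identical config + seed reproduces identical artifacts. Stages
read their inputs from the output directory when not already in memory, so
a run can resume from any cached intermediate.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allometry, backcast, ensemble, mapping, rasters, synthetic
from .errors import ConfigurationError, DataError
from .inventory import (
    WoodDensityTable,
    read_footprints,
    read_inventory,
    write_footprints,
    write_inventory,
)

SCENARIOS = {
    "include_under_threshold": "agb_incl",
    "exclude_under_threshold": "agb_excl",
}
STAGES = ["simulate", "backcast", "agb", "features", "train", "map"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "agbstack_run"
    seed: int = 0
    scenario: str = "both"  # one scenario name or "both"
    # real-data inputs; leave None to run in synthetic mode
    inventory_cycle1: str | None = None
    inventory_cycle2: str | None = None
    footprints: str | None = None
    raster_dir: str | None = None
    density_table: str | None = None
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    expected_years: tuple = (2017, 2021, 2022, 2023)
    cycle1_year: int = 2017
    train_fraction: float = 0.8
    ev_fraction: float = 0.2
    cv_folds: int = 5
    repetitions: int = 5
    n_selected_features: int = 20
    feature_selection: str = "pearson"  # "pearson" | "rfecv"
    compute_importance: bool = False
    model_grids: dict = field(default_factory=dict)  # model name -> grid
    tile_size: int = 256
    write_rasters: bool = True

    def __post_init__(self):
        if self.scenario != "both" and self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.feature_selection not in ("pearson", "rfecv"):
            raise ConfigurationError(
                f"unknown feature_selection {self.feature_selection!r}"
            )

    @property
    def synthetic_mode(self) -> bool:
        return self.inventory_cycle1 is None

    @property
    def scenarios(self) -> list:
        return list(SCENARIOS) if self.scenario == "both" else [self.scenario]

    def synthetic_config(self) -> synthetic.SyntheticConfig:
        return synthetic.SyntheticConfig(seed=self.seed, **self.synthetic)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class _Log:
    def __init__(self, path):
        self.path = Path(path)

    def write(self, stage, elapsed_s, **info):
        entry = {"stage": stage, "elapsed_s": round(elapsed_s, 3), **info}
        with self.path.open("a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")


def _out(config) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# --- individual stages ------------------------------------------------------

def stage_simulate(config: RunConfig, ctx: dict, log: _Log) -> dict:
    t0 = time.perf_counter()
    out = _out(config)
    scfg = config.synthetic_config()
    ds = synthetic.generate_dataset(scfg)
    ctx.update(cycle1=ds.cycle1, cycle2=ds.cycle2, dataset=ds, synth_cfg=scfg)
    write_inventory(ds.cycle1, out / "cycle1.csv")
    write_inventory(ds.cycle2, out / "cycle2.csv")
    ds.plot_truth.to_csv(out / "plot_truth.csv")
    if config.write_rasters:
        stack, footprints = synthetic.generate_rasters(scfg, ds.plot_truth["agb_incl_true"])
        raster_dir = out / "rasters"
        raster_dir.mkdir(exist_ok=True)
        for name, grid in stack.items():
            rasters.write_raster(grid, raster_dir / f"{name}.tif")
        write_footprints(footprints, out / "footprints.geojson", crs=scfg.crs)
        ctx.update(stack=stack, footprints=footprints)
    log.write(
        "simulate", time.perf_counter() - t0,
        n_plots=scfg.n_plots, n_cycle1=len(ds.cycle1), n_cycle2=len(ds.cycle2),
    )
    return ctx


def _load_inventories(config: RunConfig, ctx: dict, log: _Log):
    if "cycle1" in ctx:
        return
    out = _out(config)
    if config.synthetic_mode:
        for name in ("cycle1", "cycle2"):
            path = out / f"{name}.csv"
            if not path.exists():
                raise DataError(f"{path} missing: run the simulate stage first")
            ctx[name], _ = read_inventory(path, config.expected_years)
    else:
        c1, rep1 = read_inventory(config.inventory_cycle1, config.expected_years)
        c2, rep2 = read_inventory(config.inventory_cycle2, config.expected_years)
        ctx.update(cycle1=c1, cycle2=c2)
        log.write("read_inventory", 0.0, cycle1_drops=rep1, cycle2_drops=rep2)


def stage_backcast(config: RunConfig, ctx: dict, log: _Log) -> dict:
    t0 = time.perf_counter()
    out = _out(config)
    _load_inventories(config, ctx, log)
    pairs = backcast.pair_preserved(ctx["cycle1"], ctx["cycle2"])
    table, holdout = backcast.build_growth_table(
        pairs, train_fraction=config.train_fraction, seed=config.seed
    )
    validation = backcast.validate_holdout(table, holdout)
    result = backcast.backcast_entered(table, ctx["cycle2"], cycle1_year=config.cycle1_year)
    ctx.update(growth_table=table, backcast_result=result, holdout_validation=validation)
    result.detail.to_csv(out / "backcast_detail.csv", index=False)
    write_inventory(result.records, out / "backcast_records.csv")
    (out / "backcast_summary.json").write_text(
        json.dumps(
            {
                "holdout_r2": validation["r2"],
                "holdout_rmse_cm": validation["rmse_cm"],
                "n_holdout": int(len(validation["pairs"])),
                **result.summary,
            },
            indent=2,
        )
    )
    log.write(
        "backcast", time.perf_counter() - t0,
        n_pairs=len(pairs), holdout_r2=validation["r2"],
        holdout_rmse_cm=validation["rmse_cm"], **result.summary,
    )
    return ctx


def stage_agb(config: RunConfig, ctx: dict, log: _Log) -> dict:
    t0 = time.perf_counter()
    out = _out(config)
    _load_inventories(config, ctx, log)
    if "backcast_result" not in ctx:
        path = out / "backcast_records.csv"
        if not path.exists():
            raise DataError(f"{path} missing: run the backcast stage first")
        records, _ = read_inventory(path, [config.cycle1_year], allow_backcast=True)
    else:
        records = ctx["backcast_result"].records
    density = WoodDensityTable.from_csv(config.density_table)
    cycle1 = ctx["cycle1"]
    first_cycle = pd.concat(
        [cycle1.loc[cycle1["measure_type"] == "measured"], records], ignore_index=True
    )
    first_cycle = density.attach(first_cycle)
    per_plot, summary = allometry.scenario_table(first_cycle)
    ctx["plot_agb"] = per_plot
    per_plot.to_csv(out / "plot_agb.csv", index=False)
    (out / "agb_summary.json").write_text(json.dumps(summary, indent=2))
    log.write("agb", time.perf_counter() - t0, n_plots=len(per_plot),
              mean_incl=summary["including_under_threshold"]["mean"],
              mean_excl=summary["excluding_under_threshold"]["mean"])
    return ctx


def stage_features(config: RunConfig, ctx: dict, log: _Log) -> dict:
    t0 = time.perf_counter()
    out = _out(config)
    if "plot_agb" not in ctx:
        path = out / "plot_agb.csv"
        if not path.exists():
            raise DataError(f"{path} missing: run the agb stage first")
        ctx["plot_agb"] = pd.read_csv(path, dtype={"plot_id": str})
    targets = ctx["plot_agb"].set_index("plot_id")[["agb_incl", "agb_excl"]]

    raster_dir = Path(config.raster_dir) if config.raster_dir else _out(config) / "rasters"
    if "stack" not in ctx and raster_dir.exists():
        ctx["stack"] = {
            p.stem: rasters.read_raster(p) for p in sorted(raster_dir.glob("*.tif"))
        }
        ctx["footprints"] = read_footprints(
            Path(config.footprints) if config.footprints else out / "footprints.geojson"
        )
    if "stack" in ctx:
        grids = rasters.compute_feature_grids(ctx["stack"])
        ctx["feature_grids"] = grids
        transform = next(iter(ctx["stack"].values())).transform
        ctx["transform"] = transform
        table, report = rasters.extract_plot_features(grids, transform, ctx["footprints"])
        table = table.join(targets, how="inner")
    else:
        # tabular path: plan-derived features (synthetic mode, rasters disabled)
        table = synthetic.generate_feature_table(config.synthetic_config(), targets)
        report = {"n_kept": len(table), "source": "plan"}
    ctx["features"] = table
    table.to_csv(out / "features.csv")
    feature_cols = [c for c in table.columns if c in rasters.CANONICAL_FEATURES]
    (out / "features_schema.json").write_text(
        json.dumps(rasters.feature_schema(feature_cols), indent=2)
    )
    log.write("features", time.perf_counter() - t0, n_plots=len(table), report=report)
    return ctx


def _select_features(config: RunConfig, table, feature_cols, target_col):
    k = min(config.n_selected_features, len(feature_cols))
    if config.feature_selection == "pearson":
        screen = ensemble.pearson_screen(table, feature_cols, target_col)
        ranked = screen["r"].abs().sort_values(ascending=False, kind="stable")
        return list(ranked.index[:k]), {"method": "pearson_top_k", "k": k}
    per_sel, per_rank = {}, {}
    for name in ensemble.MODEL_NAMES:
        res = ensemble.rfecv_select(
            table, feature_cols, target_col, model_name=name,
            cv_folds=config.cv_folds, seed=config.seed,
        )
        per_sel[name], per_rank[name] = res["selected"], res["ranking"]
    selected, sel_log = ensemble.consensus_features(per_sel, per_rank, target_size=k)
    return selected, {"method": "rfecv_consensus", **sel_log}


def stage_train(config: RunConfig, ctx: dict, log: _Log) -> dict:
    t0 = time.perf_counter()
    out = _out(config)
    if "features" not in ctx:
        path = out / "features.csv"
        if not path.exists():
            raise DataError(f"{path} missing: run the features stage first")
        ctx["features"] = pd.read_csv(path, dtype={"plot_id": str}).set_index("plot_id")
    table = ctx["features"]
    feature_cols = [c for c in table.columns if c in rasters.CANONICAL_FEATURES]
    specs = dict(ensemble.DEFAULT_SPECS)
    for name, grid in config.model_grids.items():
        tuned = ensemble.grid_search_tune(
            table, feature_cols, SCENARIOS[config.scenarios[0]], name, grid,
            cv_folds=config.cv_folds, seed=config.seed,
        )
        specs[name] = tuned.chosen
    ctx["reports"] = {}
    for scenario in config.scenarios:
        target_col = SCENARIOS[scenario]
        selected, sel_log = _select_features(config, table, feature_cols, target_col)
        report = ensemble.run_protocols(
            table, selected, target_col, specs=specs,
            ev_fraction=config.ev_fraction, cv_folds=config.cv_folds,
            repetitions=config.repetitions, seed=config.seed, scenario=scenario,
            compute_importance=config.compute_importance,
        )
        ctx["reports"][scenario] = report
        report["cv"].to_csv(out / f"eval_cv_{scenario}.csv")
        report["ev"].to_csv(out / f"eval_ev_{scenario}.csv")
        model = report["stacked_model"]
        bundle = {
            "scenario": scenario,
            "selected_features": model.feature_names,
            "selection": sel_log,
            "specs": model.specs,
            "meta_coefficients": model.meta_coefficients,
            "meta_intercept": model.meta_intercept,
            "ridge_alpha": float(model.meta.alpha),
        }
        (out / f"model_{scenario}.json").write_text(json.dumps(bundle, indent=2))
        log.write(
            "train", time.perf_counter() - t0, scenario=scenario,
            selected=len(selected),
            ev_r2_stacked=float(report["ev"].loc["stacked", "r2"]),
            ev_rmse_stacked=float(report["ev"].loc["stacked", "rmse"]),
        )
    return ctx


def stage_map(config: RunConfig, ctx: dict, log: _Log) -> dict:
    t0 = time.perf_counter()
    out = _out(config)
    if "reports" not in ctx:
        raise DataError("run the train stage first (models are kept in memory)")
    if "feature_grids" not in ctx:
        raise DataError("mapping needs raster feature grids (enable write_rasters)")
    pixel_area_ha = (ctx["transform"].dx * ctx["transform"].dy) / 10_000.0
    ctx["maps"] = {}
    for scenario, report in ctx["reports"].items():
        model = report["stacked_model"]
        pmap = mapping.predict_map(
            model, ctx["feature_grids"], ctx["transform"], tile_size=config.tile_size
        )
        summary = mapping.map_summary(pmap, pixel_area_ha)
        ctx["maps"][scenario] = (pmap, summary)
        rasters.write_raster(pmap.agb, out / f"agb_map_{scenario}.tif")
        rasters.write_raster(pmap.uncertainty, out / f"uncertainty_map_{scenario}.tif")
        (out / f"map_summary_{scenario}.json").write_text(
            json.dumps({**summary, "provenance": pmap.provenance}, indent=2)
        )
        log.write("map", time.perf_counter() - t0, scenario=scenario, **summary)
    return ctx


def run_pipeline(config: RunConfig, stages=None) -> Path:
    """Run the requested stages (default: all) and return the run directory."""
    out = _out(config)
    (out / "resolved_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str)
    )
    log = _Log(out / "run_log.jsonl")
    stages = STAGES if stages is None else stages
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stages: {unknown}")
    ctx: dict = {}
    runners = {
        "simulate": stage_simulate, "backcast": stage_backcast, "agb": stage_agb,
        "features": stage_features, "train": stage_train, "map": stage_map,
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "simulate" and not config.synthetic_mode:
            continue
        try:
            runners[stage](config, ctx, log)
        except Exception:
            log.write(stage, 0.0, status="failed")
            raise
    return out


def run_tabular_benchmark(
    synth_cfg: synthetic.SyntheticConfig | None = None,
    seed: int = 0,
    ev_fraction: float = 0.2,
    n_selected_features: int = 20,
    specs: dict | None = None,
    cv_folds: int = 5,
) -> dict:
    """Run the modelling chain in memory on one seeded synthetic draw.

    Generates the dataset, back-casts entered trees, computes plot AGB under
    both scenarios, derives the plan-based feature table, selects the top
    features by absolute Pearson correlation and fits/evaluates the stacked
    ensemble under the external-verification protocol for each scenario.
    Used by higher-level reporting; returns every intermediate needed to
    audit the run.
    """
    cfg = synthetic.SyntheticConfig(seed=seed) if synth_cfg is None else synth_cfg
    ds = synthetic.generate_dataset(cfg)
    pairs = backcast.pair_preserved(ds.cycle1, ds.cycle2)
    table, holdout = backcast.build_growth_table(pairs, seed=seed)
    validation = backcast.validate_holdout(table, holdout)
    result = backcast.backcast_entered(table, ds.cycle2, cycle1_year=cfg.cycle1_year)
    density = WoodDensityTable.from_csv()
    cycle1 = ds.cycle1
    first_cycle = density.attach(
        pd.concat(
            [cycle1.loc[cycle1["measure_type"] == "measured"], result.records],
            ignore_index=True,
        )
    )
    per_plot, agb_summary = allometry.scenario_table(first_cycle)
    targets = per_plot.set_index("plot_id")[["agb_incl", "agb_excl"]]
    features = synthetic.generate_feature_table(cfg, targets)
    feature_cols = [c for c in features.columns if c in rasters.CANONICAL_FEATURES]

    evaluations = {}
    models = {}
    for scenario, target_col in SCENARIOS.items():
        screen = ensemble.pearson_screen(features, feature_cols, target_col)
        ranked = screen["r"].abs().sort_values(ascending=False, kind="stable")
        selected = list(ranked.index[: min(n_selected_features, len(feature_cols))])
        mask_ev = ensemble.ev_split(len(features), ev_fraction, seed)
        model = ensemble.fit_stacked(
            features.loc[~mask_ev], selected, target_col, specs=specs,
            cv_folds=cv_folds, seed=seed, scenario=scenario,
        )
        external = features.loc[mask_ev]
        y_ev = external[target_col].to_numpy(dtype=float)
        base = model.base_predictions(external)
        scores = {
            name: ensemble.evaluate(y_ev, base[:, j])
            for j, name in enumerate(model.specs)
        }
        scores["stacked"] = ensemble.evaluate(y_ev, model.predict(external)[0])
        evaluations[scenario] = scores
        models[scenario] = model
    return {
        "config": cfg,
        "dataset": ds,
        "growth_table": table,
        "holdout_validation": validation,
        "backcast_result": result,
        "plot_agb": per_plot,
        "agb_summary": agb_summary,
        "features": features,
        "evaluations": evaluations,
        "models": models,
    }


def demo_config(out_dir: str = "agbstack_demo", seed: int = 0) -> RunConfig:
    """A small synthetic configuration that runs end-to-end in minutes."""
    return RunConfig(
        out_dir=out_dir,
        seed=seed,
        synthetic={"n_plots": 120, "raster_shape": (100, 100)},
        repetitions=3,
        scenario="both",
    )
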