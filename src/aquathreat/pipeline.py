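"""End-to-end orchestration on a synthetic world.

Stages: world generation -> species filtering -> extreme indicators
(baseline + every ensemble member) -> species thresholds -> exposure
under both dispersal assumptions -> ensemble/PAF/watershed aggregation
-> phylogenetic trait regression.  Every stage writes plain CSV (plus
newick/JSON) into the output directory and the manifest records seeds
and per-file checksums, so reruns with the same config are verifiable
as bit-identical.

Weather noise is drawn once per world (from the world seed) and shared
by all scenarios, so ensemble members differ exactly by their
temperature-delta and flow-scale fields; this keeps the scenario family
nested in warming level.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import aggregation, dispersal, exposure, hydro_extremes, phylo_traits, range_io
from . import synthetic_world as world
from .thresholds import SpeciesThresholds, derive_species_thresholds
from .synthetic_world import WARMING_LEVELS

logger = logging.getLogger("aquathreat.pipeline")


@dataclass
class RunConfig:
    """One synthetic end-to-end run; all fields have workable defaults."""

    out_dir: str = "aquathreat_run"
    seed: int = 0
    # world
    n_rows: int = 26
    n_cols: int = 26
    n_basins: int = 6
    n_ecoregions: int = 4
    n_species: int = 80
    n_years: int = 30
    weeks_per_year: int = 52
    noise_sd: float = 0.5
    zero_flow_prob: float = 0.01
    base_temp: float = 15.0
    temp_amplitude: float = 8.0
    base_flow: float = 20.0
    flow_amplitude: float = 15.0
    temp_gradient: float = 25.0   # deg C across the grid's latitude span
    warming_levels: Sequence[float] = WARMING_LEVELS
    members_per_level: int = 3
    drought_fraction: float = 0.2
    # filtering / thresholds
    min_cells: int = 10
    min_unit_area_km2: float = 1000.0
    zero_flow_tolerance: float = 0.0
    # weight threshold quantiles by cell area so the 2.5% robustness
    # margin is guaranteed in km^2 terms (equals cell counts on
    # equal-area grids)
    area_weighted_thresholds: bool = True
    # regression
    run_pgls: bool = True
    pgls_warming_level: float = 3.2
    importance_iterations: int = 25
    response_offset: float = 0.01
    planted_beta: dict = field(
        default_factory=lambda: {"intercept": 1.0, "log10_range_km2": -0.4}
    )
    planted_lambda: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    grid: world.GridDefinition
    scenarios: list[world.ScenarioSpec]
    ranges: list[range_io.SpeciesRange]
    exclusions: pd.DataFrame
    baseline_extremes: pd.DataFrame
    thresholds: pd.DataFrame
    exposure: pd.DataFrame                      # long table, both dispersal modes
    units: dispersal.SubBasinUnits
    expanded: dict[str, dispersal.ExpandedRange]
    summaries: list[aggregation.EnsembleSummary]
    paf_maps: dict[tuple[float, str, str], aggregation.PafMap]  # (level, dispersal, group)
    watershed: pd.DataFrame
    pgls_fits: dict[str, phylo_traits.PglsFit]
    importance: dict[str, phylo_traits.ImportanceScores]
    traits: pd.DataFrame
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, manifest: dict, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.10g")
    manifest["files"][path.name] = _sha256(path)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage; outputs land under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"seed": config.seed, "config": asdict(config), "files": {}, "stages": []}
    manifest["config"]["warming_levels"] = list(config.warming_levels)

    def stage(name: str) -> None:
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    # --- world -----------------------------------------------------------
    stage("world")
    grid = world.generate_grid(
        config.n_rows, config.n_cols, config.n_basins, config.n_ecoregions,
        seed=int(rng.integers(2**31 - 1)),
    )
    scenarios, drought_cells = world.generate_scenarios(
        grid,
        seed=int(rng.integers(2**31 - 1)),
        warming_levels=config.warming_levels,
        members_per_level=config.members_per_level,
        drought_fraction=config.drought_fraction,
    )
    raw_ranges = world.generate_species_ranges(
        grid, config.n_species, seed=int(rng.integers(2**31 - 1))
    )
    traits, tree, truth = world.generate_traits_and_tree(
        sorted(raw_ranges),
        beta=config.planted_beta,
        lam=config.planted_lambda,
        noise_sd=0.5,
        seed=int(rng.integers(2**31 - 1)),
        range_sizes_km2={sp: grid.area_of(c) for sp, c in raw_ranges.items()},
    )
    _write_csv(grid.to_frame(), out / "grid.csv", manifest)
    _write_csv(traits, out / "traits.csv", manifest)
    tree_path = out / "tree.nwk"
    tree.write(path=str(tree_path), schema="newick")
    manifest["files"]["tree.nwk"] = _sha256(tree_path)

    # --- filtering -------------------------------------------------------
    stage("filter_species")
    habitat_by_sp = dict(zip(traits["species_id"], traits["habitat_type"]))
    all_ranges = [
        range_io.make_range(sp, cells, grid, habitat_by_sp.get(sp, "lotic"))
        for sp, cells in sorted(raw_ranges.items())
    ]
    ranges, exclusions = range_io.filter_species(all_ranges, min_cells=config.min_cells)
    if not ranges:
        raise RuntimeError("filter_species: no species retained")
    _write_csv(range_io.ranges_to_frame(ranges, grid), out / "ranges.csv", manifest)
    _write_csv(exclusions, out / "exclusion_report.tsv", manifest)

    # --- extremes --------------------------------------------------------
    stage("extremes")
    series_seed = int(rng.integers(2**31 - 1))  # shared weather noise
    extremes_by_scenario: dict[str, pd.DataFrame] = {}
    for scen in scenarios:
        flow, temp = world.generate_weekly_series(
            grid,
            scen,
            n_years=config.n_years,
            weeks_per_year=config.weeks_per_year,
            base_temp=config.base_temp,
            temp_amplitude=config.temp_amplitude,
            base_flow=config.base_flow,
            flow_amplitude=config.flow_amplitude,
            noise_sd=config.noise_sd,
            zero_flow_prob=config.zero_flow_prob,
            temp_gradient=config.temp_gradient,
            seed=series_seed,
        )
        extremes_by_scenario[scen.scenario_id] = hydro_extremes.compute_grid_extremes(
            grid, flow, temp, scenario_id=scen.scenario_id,
            zero_flow_tolerance=config.zero_flow_tolerance,
        )
    baseline_extremes = extremes_by_scenario["baseline"]
    _write_csv(
        pd.concat(extremes_by_scenario.values()).reset_index(),
        out / "extremes.csv", manifest,
    )

    # --- thresholds ------------------------------------------------------
    stage("thresholds")
    range_sets = {r.species_id: r.cells for r in ranges}
    area_series = (
        pd.Series(grid.cell_area.ravel(), index=pd.RangeIndex(grid.n_cells, name="cell"))
        if config.area_weighted_thresholds
        else None
    )
    thr_table = pd.DataFrame(
        [
            derive_species_thresholds(
                sp, cells, baseline_extremes, area_weights=area_series
            ).as_series()
            for sp, cells in sorted(range_sets.items())
        ]
    )
    thr_table.index.name = "species_id"
    _write_csv(thr_table.reset_index(), out / "thresholds.csv", manifest)
    thr_objs = {
        sp: SpeciesThresholds(species_id=sp, **row.to_dict())
        for sp, row in thr_table.iterrows()
    }

    # --- dispersal units + expansion -------------------------------------
    stage("subbasins")
    units = dispersal.delineate_subbasins(grid, min_unit_area=config.min_unit_area_km2)
    expanded = {
        sp: dispersal.expand_range(sp, cells, units, baseline_extremes, thr_objs[sp], grid)
        for sp, cells in sorted(range_sets.items())
    }
    _write_csv(
        pd.DataFrame({"cell": np.arange(grid.n_cells), "unit_id": units.unit_id}),
        out / "subbasin_units.csv", manifest,
    )

    # --- exposure (both dispersal modes) ----------------------------------
    stage("exposure")
    results: list[exposure.ExposureResult] = []
    dispersal_col: list[str] = []
    level_col: list[float] = []
    grouped_by: dict[tuple[str, str], pd.DataFrame] = {}  # (species, scenario) -> group flags
    future = [s for s in scenarios if not s.is_baseline]
    for scen in future:
        metrics = extremes_by_scenario[scen.scenario_id]
        for sp, cells in sorted(range_sets.items()):
            universe = sorted(cells | expanded[sp].expanded_cells)
            flags = exposure.flag_cell_exceedance(metrics.loc[universe], thr_objs[sp])
            grouped = exposure.group_flags(flags)
            grouped_by[(sp, scen.scenario_id)] = grouped
            for res in exposure.range_threatened(
                sp, scen.scenario_id, cells, grouped, grid
            ).values():
                results.append(res)
                dispersal_col.append("none")
                level_col.append(scen.warming_level)
            for res in dispersal.range_threatened_maximal(
                expanded[sp], scen.scenario_id, grouped, grid
            ).values():
                results.append(res)
                dispersal_col.append("maximal")
                level_col.append(scen.warming_level)
    exposure_df = exposure.exposure_table(results)
    exposure_df["dispersal"] = dispersal_col
    exposure_df["warming_level"] = level_col
    _write_csv(exposure_df, out / "exposure.csv", manifest)

    # --- aggregation ------------------------------------------------------
    stage("aggregation")
    summaries = []
    paf_maps: dict[tuple[float, str, str], aggregation.PafMap] = {}
    watershed_rows = []
    for disp in ("none", "maximal"):
        pools = {
            sp: (cells if disp == "none" else cells | expanded[sp].expanded_cells)
            for sp, cells in range_sets.items()
        }
        for level in config.warming_levels:
            summaries.append(
                aggregation.summarize_ensemble(exposure_df, level, disp)
            )
            members = [s.scenario_id for s in future if s.warming_level == level]
            for group in ("any", "temperature", "flow", "both"):
                exceed = {
                    (sp, m): frozenset(
                        int(c)
                        for c in grouped_by[(sp, m)].index[grouped_by[(sp, m)][group]]
                        if c in pools[sp]
                    )
                    for sp in pools
                    for m in members
                }
                pmap = aggregation.cell_paf(
                    pools, exceed, members, grid.n_cells,
                    warming_level=level, variable_group=group,
                )
                paf_maps[(level, disp, group)] = pmap
                if group == "any":
                    ws = aggregation.watershed_paf(pmap, grid.basin_id)
                    ws["warming_level"] = level
                    ws["dispersal"] = disp
                    watershed_rows.append(ws.reset_index())
    watershed = pd.concat(watershed_rows, ignore_index=True)
    _write_csv(watershed, out / "watershed_paf.csv", manifest)
    summary_df = pd.DataFrame(
        {
            "warming_level": [s.warming_level for s in summaries],
            "dispersal": [s.dispersal for s in summaries],
            "fraction_over_half_mean": [s.fraction_over_half_mean for s in summaries],
            "fraction_over_half_sd": [s.fraction_over_half_sd for s in summaries],
        }
    )
    _write_csv(summary_df, out / "ensemble_summary.csv", manifest)
    paf_long = pd.concat(
        [
            pd.DataFrame(
                {
                    "cell": np.arange(grid.n_cells),
                    "paf": pmap.paf,
                    "s_present": pmap.s_present,
                    "warming_level": level,
                    "dispersal": disp,
                    "variable_group": group,
                }
            )
            for (level, disp, group), pmap in paf_maps.items()
        ],
        ignore_index=True,
    )
    _write_csv(paf_long[paf_long["s_present"] > 0], out / "paf.csv", manifest)

    # --- phylogenetic regression ------------------------------------------
    fits: dict[str, phylo_traits.PglsFit] = {}
    importance: dict[str, phylo_traits.ImportanceScores] = {}
    if config.run_pgls:
        stage("pgls")
        retained = {r.species_id for r in ranges}
        fit_traits = traits[traits["species_id"].isin(retained)].reset_index(drop=True)
        level = config.pgls_warming_level
        for disp in ("none", "maximal"):
            summary = next(
                s for s in summaries if s.warming_level == level and s.dispersal == disp
            )
            tab = fit_traits.copy()
            tab["response"] = phylo_traits.log_response(
                summary.mean_rt_by_species.loc[tab["species_id"]].to_numpy(),
                offset=config.response_offset,
            )
            fit = phylo_traits.fit_pgls(tab, tree, response="response")
            fits[disp] = fit
            importance[disp] = phylo_traits.variable_importance(
                fit, tab, n_iterations=config.importance_iterations,
                seed=int(rng.integers(2**31 - 1)),
            )
            fit_out = fit.summary().reset_index()
            fit_out["lambda"] = fit.lambda_
            fit_out["pearson_r"] = fit.pearson_r_pred_obs
            _write_csv(fit_out, out / f"pgls_{disp}.csv", manifest)
            imp = importance[disp]
            _write_csv(
                pd.DataFrame({"mean": imp.mean, "sd": imp.sd}).reset_index(names="covariate"),
                out / f"importance_{disp}.csv", manifest,
            )
    else:
        logger.info("pgls stage skipped (run_pgls is false)")
        manifest["stages"].append("pgls:skipped")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        grid=grid,
        scenarios=scenarios,
        ranges=ranges,
        exclusions=exclusions,
        baseline_extremes=baseline_extremes,
        thresholds=thr_table,
        exposure=exposure_df,
        units=units,
        expanded=expanded,
        summaries=summaries,
        paf_maps=paf_maps,
        watershed=watershed,
        pgls_fits=fits,
        importance=importance,
        traits=traits,
        manifest=manifest,
    )
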