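"""End-to-end pipeline: synthetic island → sediment → plume → drivers →
reef models → predictions → impact assessment → prioritization.

Every stage writes its outputs under the run directory; the run is fully
deterministic given the configuration seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ridge2reef import (
    coastal_plume,
    impact_assessment,
    marine_drivers,
    prioritization,
    reef_models,
    scenario_builder,
    sediment_export,
    synthetic_island,
)
from ridge2reef.core_io.config import PipelineConfig
from ridge2reef.core_io.grid import Grid, PointTable
from ridge2reef.core_io.io import (
    write_geojson_geometry,
    write_grid,
    write_points_geojson,
)

log = logging.getLogger("ridge2reef")

#: Continuous drivers offered to the reef models (aspect itself is circular
#: and enters through northness/eastness instead).
MODEL_DRIVERS = [
    "tss", "depth", "dist_shore", "bpi_60", "bpi_240", "slope",
    "slope_of_slope", "curv_plan", "curv_prof", "northness", "eastness",
    "aspect_circ_sd", "contiguity", "fractal_dim", "proximity", "shannon",
]


@dataclass
class PipelineResult:
    outdir: str
    bundle: synthetic_island.IslandBundle
    surveys: PointTable
    sediment: dict[str, sediment_export.SedimentResult]
    watersheds: sediment_export.WatershedSet
    plumes: dict[str, coastal_plume.PlumeField]
    models: dict[str, reef_models.FittedIndicatorModel]
    predictions: dict[str, dict[str, Grid]]
    impact_summary: pd.DataFrame
    linkage: prioritization.LinkageResult | None
    priority_mask: Grid | None
    extras: dict = field(default_factory=dict)


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig, outdir: str) -> PipelineResult:
    """Run all stages on the synthetic island and write outputs to
    ``outdir``.  Any stage failure aborts with the stage name attached."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    config.to_yaml(os.path.join(outdir, "config.yml"))
    stage = "synth"
    try:
        # ---- synthetic island ------------------------------------------
        _stage(stage)
        bundle = synthetic_island.make_island(config.seed, config.synth.size)
        surveys = synthetic_island.make_reef_surveys(
            bundle, bundle.truth, config.synth.n_sites,
            config.synth.noise_sd, config.seed + 1,
        )
        write_synth_outputs(bundle, surveys, os.path.join(outdir, "synth"))

        # ---- sediment export per land-use scenario ----------------------
        stage = "sediment"
        _stage(stage)
        scenarios = ["current"]
        if config.scenario != "current":
            scenarios.append(config.scenario)
        sediment: dict[str, sediment_export.SedimentResult] = {}
        watersheds = None
        for scen in scenarios:
            lu, c_grid, ledger = scenario_builder.apply_landuse_scenario(
                bundle.land_cover, bundle.luc, bundle.concessions, scen,
                config.c_factors,
            )
            c_grid = c_grid.like(
                np.where(bundle.dem.mask(), c_grid.values, np.nan)
            )
            result, ws, streams, facc = sediment_export.run_sediment(
                bundle.dem, bundle.rain_monthly, bundle.k_grid, c_grid,
                params=config.sdr, erosivity_mode=config.erosivity_mode,
                pour_points=bundle.pour_points,
            )
            sediment[scen] = result
            watersheds = ws
            sdir = os.path.join(outdir, "sediment", scen)
            os.makedirs(sdir, exist_ok=True)
            for name, grid in (
                ("soil_loss", result.soil_loss), ("ic", result.ic),
                ("sdr", result.sdr), ("export", result.export),
                ("watersheds", ws.labels), ("streams", streams),
                ("land_use", lu), ("c_factor", c_grid),
            ):
                write_grid(grid, os.path.join(sdir, f"{name}.tif"))
            result.loads_frame(ws).to_csv(
                os.path.join(sdir, "watershed_loads.csv"), index=False
            )
            ledger.to_csv(os.path.join(sdir, "scenario_ledger.csv"), index=False)
        flow_accum = facc

        # ---- plumes ------------------------------------------------------
        stage = "plume"
        _stage(stage)
        plumes: dict[str, coastal_plume.PlumeField] = {}
        for scen in scenarios:
            pf = coastal_plume.run_plume(
                sediment[scen].watershed_loads, bundle.pour_points,
                bundle.stack["depth"], bundle.stack["dist_shore"],
                bundle.wind_exposure, config.plume,
            )
            plumes[scen] = pf
            pdir = os.path.join(outdir, "plume", scen)
            os.makedirs(pdir, exist_ok=True)
            for wid, grid in pf.plumes.items():
                write_grid(grid, os.path.join(pdir, f"plume_{wid}.tif"))
            write_grid(pf.tss, os.path.join(pdir, "tss.tif"))
            pf.totals_frame().to_csv(
                os.path.join(pdir, "totals.csv"), index=False
            )

        # ---- marine drivers ---------------------------------------------
        stage = "drivers"
        _stage(stage)
        ddir = os.path.join(outdir, "drivers")
        os.makedirs(ddir, exist_ok=True)
        for name in bundle.stack.names():
            write_grid(bundle.stack[name], os.path.join(ddir, f"{name}.tif"))
        bundle.stack.manifest().to_csv(
            os.path.join(ddir, "manifest.csv"), index=False
        )

        # ---- reef models -------------------------------------------------
        stage = "fit"
        _stage(stage)
        grids = {n: bundle.stack[n] for n in MODEL_DRIVERS if n in bundle.stack.grids}
        grids["tss"] = plumes["current"].tss
        frame = reef_models.sample_predictors(grids, surveys)
        models = reef_models.fit_hierarchy(
            frame, [n for n in grids], config.brt, config.r_max
        )
        write_model_outputs(models, frame, os.path.join(outdir, "models"))

        # ---- predictions -------------------------------------------------
        stage = "predict"
        _stage(stage)
        predictions: dict[str, dict[str, Grid]] = {}
        depth_grid = bundle.stack["depth"]
        variants = {"present": ("current", "none")}
        if config.scenario != "current":
            variants["landuse"] = (config.scenario, "none")
        if config.bleaching != "none":
            variants["bleaching"] = ("current", config.bleaching)
            if config.scenario != "current":
                variants["combined"] = (config.scenario, config.bleaching)
        for label, (scen, bleach) in variants.items():
            pgrids = dict(grids)
            pgrids["tss"] = plumes[scen].tss
            maps = predict_indicators(
                models, pgrids, depth_grid, bleach, config
            )
            predictions[label] = maps
            vdir = os.path.join(outdir, "predict", label)
            os.makedirs(vdir, exist_ok=True)
            for ind, grid in maps.items():
                write_grid(grid, os.path.join(vdir, f"{ind}.tif"))

        # ---- impact assessment ------------------------------------------
        stage = "assess"
        _stage(stage)
        adir = os.path.join(outdir, "assess")
        os.makedirs(adir, exist_ok=True)
        sig_params = impact_assessment.SigDiffParams(alpha=config.alpha)
        all_inds = list(models)
        rows = []
        masks: dict[str, dict[str, tuple[Grid, Grid]]] = {}
        for label in [v for v in predictions if v != "present"]:
            results = {}
            for ind in all_inds:
                _, mask, diff = impact_assessment.sig_diff(
                    predictions[label][ind], predictions["present"][ind],
                    sig_params,
                )
                results[ind] = (mask, diff)
            masks[label] = results
            summary = impact_assessment.summarize_impact(results)
            summary.insert(0, "scenario", label)
            rows.append(summary)
        if "landuse" in masks and "bleaching" in masks:
            for ind in all_inds:
                cat = impact_assessment.overlay_scenarios(
                    masks["landuse"][ind][0], masks["bleaching"][ind][0]
                )
                write_grid(cat, os.path.join(adir, f"category_{ind}.tif"))
        impact_summary = (
            pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        )
        impact_summary.to_csv(
            os.path.join(adir, "impact_summary.csv"), index=False
        )

        # ---- prioritization ---------------------------------------------
        stage = "prioritize"
        _stage(stage)
        linkage = None
        priority_mask = None
        if masks:
            label = "landuse" if "landuse" in masks else next(iter(masks))
            # union of per-indicator significant reef cells
            union = np.zeros(depth_grid.shape, dtype=np.int32)
            for ind in all_inds:
                union |= masks[label][ind][0].values.astype(np.int32)
            union_grid = Grid(union, depth_grid.cell_size, depth_grid.origin,
                              0, depth_grid.crs)
            scen_plumes = plumes[scenarios[-1]].plumes
            if union.any():
                linkage = prioritization.link_watersheds(
                    union_grid, scen_plumes, config.linkage_threshold
                )
                mode = "landuse" if config.scenario != "current" else "climate"
                priority_mask = prioritization.priority_land_areas(
                    sediment["current"].export, watersheds, linkage.linked,
                    mode=mode, frac=config.priority_export_fraction,
                    export_scenario=(
                        sediment[config.scenario].export
                        if config.scenario != "current" else None
                    ),
                    sigdiff_params=sig_params, flow_accum=flow_accum,
                )
                pdir = os.path.join(outdir, "prioritize")
                os.makedirs(pdir, exist_ok=True)
                linkage.frame().to_csv(
                    os.path.join(pdir, "linkage.csv"), index=False
                )
                write_grid(priority_mask, os.path.join(pdir, "priority_mask.tif"))
                write_grid(union_grid, os.path.join(pdir, "significant_reef.tif"))
                poly = prioritization.buffer_priority(
                    priority_mask, config.buffer_distance,
                    land_mask=bundle.dem.mask(),
                )
                write_geojson_geometry(
                    os.path.join(pdir, "priority_buffered.geojson"), poly
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        outdir=outdir, bundle=bundle, surveys=surveys, sediment=sediment,
        watersheds=watersheds, plumes=plumes, models=models,
        predictions=predictions, impact_summary=impact_summary,
        linkage=linkage, priority_mask=priority_mask,
    )


def predict_indicators(
    models: dict[str, reef_models.FittedIndicatorModel],
    grids: dict[str, Grid],
    depth_grid: Grid,
    bleaching: str,
    config: PipelineConfig,
) -> dict[str, Grid]:
    """Predict benthic maps, apply bleaching to coral, then predict fish
    from the (adjusted) benthic maps."""
    maps: dict[str, Grid] = {}
    for ind in reef_models.BENTHIC_INDICATORS:
        maps[ind] = reef_models.predict_map(
            models[ind], grids, config.max_predict_depth
        )
    if bleaching != "none":
        spec = scenario_builder.ScenarioSpec(bleaching=bleaching)
        maps["coral"] = scenario_builder.apply_bleaching(
            maps["coral"], depth_grid, spec
        )
    fish_grids = dict(grids)
    fish_grids.update({b: maps[b] for b in reef_models.BENTHIC_INDICATORS})
    for ind in reef_models.FISH_INDICATORS:
        maps[ind] = reef_models.predict_map(
            models[ind], fish_grids, config.max_predict_depth
        )
    return maps


def write_synth_outputs(
    bundle: synthetic_island.IslandBundle,
    surveys: PointTable,
    outdir: str,
) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_grid(bundle.dem, os.path.join(outdir, "dem.tif"))
    write_grid(bundle.land_cover, os.path.join(outdir, "land_cover.tif"))
    write_grid(bundle.luc, os.path.join(outdir, "luc.tif"))
    write_grid(bundle.concessions, os.path.join(outdir, "concessions.tif"))
    write_grid(bundle.k_grid, os.path.join(outdir, "k.tif"))
    write_grid(bundle.bathy, os.path.join(outdir, "bathy.tif"))
    write_grid(bundle.habitat, os.path.join(outdir, "habitat.tif"))
    for i, g in enumerate(bundle.rain_monthly, start=1):
        write_grid(g, os.path.join(outdir, f"rain_{i:02d}.tif"))
    write_points_geojson(
        os.path.join(outdir, "pour_points.geojson"),
        [bundle.pour_points[w] for w in sorted(bundle.pour_points)],
        [{"watershed_id": w} for w in sorted(bundle.pour_points)],
    )
    surveys.to_frame().to_csv(os.path.join(outdir, "reef_surveys.csv"), index=False)


def write_model_outputs(
    models: dict[str, reef_models.FittedIndicatorModel],
    frame: pd.DataFrame,
    outdir: str,
) -> None:
    os.makedirs(outdir, exist_ok=True)
    diag_rows, infl_rows, curve_rows = [], [], []
    for ind, m in models.items():
        resid_p = np.nan
        moran_i = np.nan
        try:
            z = reef_models.transform_response(
                frame[ind].to_numpy(float), m.transform
            )
            pred = m.estimator.predict(frame[m.predictors].to_numpy(float))
            moran_i, resid_p = reef_models.moran_residuals(
                z - pred, frame["x"].to_numpy(), frame["y"].to_numpy()
            )
        except ValueError:
            pass
        diag_rows.append(
            {
                "indicator": ind, "transform": m.transform,
                "learning_rate": m.learning_rate,
                "tree_complexity": m.tree_complexity,
                "bag_fraction": m.bag_fraction, "n_trees": m.n_trees,
                "pde": m.pde, "cv_pde": m.cv_pde,
                "moran_i": moran_i, "moran_p": resid_p,
            }
        )
        for p, v in m.relative_influence.items():
            infl_rows.append({"indicator": ind, "predictor": p, "influence": v})
        curves = m.response_curves.copy()
        curves.insert(0, "indicator", ind)
        curve_rows.append(curves)
        meta = {
            "indicator": ind, "transform": m.transform,
            "predictors": m.predictors, "n_trees": m.n_trees,
            "learning_rate": m.learning_rate,
            "tree_complexity": m.tree_complexity,
            "bag_fraction": m.bag_fraction,
            "pde": m.pde, "cv_pde": m.cv_pde,
            "relative_influence": m.relative_influence,
            "training_digest": m.training_digest,
        }
        with open(os.path.join(outdir, f"{ind}.json"), "w") as fh:
            json.dump(meta, fh, indent=1)
    pd.DataFrame(diag_rows).to_csv(
        os.path.join(outdir, "diagnostics.csv"), index=False
    )
    pd.DataFrame(infl_rows).to_csv(
        os.path.join(outdir, "influences.csv"), index=False
    )
    pd.concat(curve_rows, ignore_index=True).to_csv(
        os.path.join(outdir, "response_curves.csv"), index=False
    )
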