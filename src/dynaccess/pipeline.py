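"""End-to-end pipeline: inputs -> routing -> fusion -> ratios -> stats.

Composes the library modules into the full analysis: build the
travel-time graph, route every fused grid cell to its closest ED,
summarize static population by accessibility band and urban class,
compute static/dynamic share ratios across temporal strata, and test
catchment-level differences for spatial clustering (Moran's I) and
between-level effects (ANOVA + Tukey).  Every artifact is written to the
output directory together with a manifest that reconstructs the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, accessibility, io, ratios, roads, spatial, synthetic
from .config import PipelineConfig
from .fusion import attach_urban_class, fuse_grids

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "simulate_inputs"]


@dataclass
class PipelineResult:
    fused: pd.DataFrame  # incl. band, travel_time_min, reachable, ed_id
    eds: pd.DataFrame
    band_summary: accessibility.BandSummary
    ratio_table: pd.DataFrame
    catchment_summaries: dict[tuple[int, int], pd.DataFrame]
    moran: dict[tuple[int, int], spatial.MoranResult | None]
    anova: dict[tuple[int, int], spatial.AnovaResult | None]
    tukey: dict[tuple[int, int], list[spatial.TukeyPair]]
    manifest: dict


def simulate_inputs(scenario) -> dict:
    """Generate the full synthetic input bundle for a scenario."""
    static = synthetic.generate_static_grid(scenario)
    return {
        "static": static,
        "classes": synthetic.assign_urban_classes(static, scenario),
        "segments": synthetic.generate_road_network(scenario),
        "eds": synthetic.generate_eds(static, scenario),
        "dynamic_obs": synthetic.generate_dynamic_observations(static, scenario),
    }


def _load_inputs(config: PipelineConfig) -> dict:
    if config.simulate is not None:
        return simulate_inputs(config.simulate)
    dynamic = io.read_grid_geojson(config.dynamic_grid_path)
    return {
        "static": io.read_grid_geojson(config.static_grid_path),
        "classes": io.read_classes_csv(config.classes_path),
        "segments": io.read_roads_geojson(config.roads_path),
        "eds": io.read_eds_geojson(config.eds_path),
        "dynamic_obs": (
            dynamic,
            io.read_observations_csv(config.observations_path, dynamic),
        ),
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the whole analysis; write artifacts when ``outdir`` is given."""
    inputs = _load_inputs(config)
    static, classes, eds = inputs["static"], inputs["classes"], inputs["eds"]
    dynamic, observations = inputs["dynamic_obs"]

    segments = roads.filter_walking_roads(
        roads.split_segments_at_intersections(inputs["segments"])
    )
    graph = roads.build_graph(segments)

    fused = attach_urban_class(fuse_grids(static, dynamic), static, classes)
    snapped = roads.snap_cells(fused, graph, config.max_snap_m)
    assignments = roads.closest_facility(graph, eds, snapped, config.max_snap_m)
    fused = fused.merge(
        assignments[["cell_id", "travel_time_min", "ed_id", "reachable"]], on="cell_id"
    )
    n_omitted = int((~fused["reachable"]).sum())
    logger.info(
        "%d of %d fused cells omitted (%.1f%%); %d included",
        n_omitted,
        len(fused),
        100.0 * n_omitted / len(fused),
        len(fused) - n_omitted,
    )

    edges = tuple(config.band_edges)
    labels = accessibility.band_labels(edges)
    reach = fused["reachable"]
    codes = np.full(len(fused), -1)
    codes[reach.to_numpy()] = np.digitize(
        fused.loc[reach, "travel_time_min"].to_numpy(), edges, right=False
    )
    fused["band"] = pd.Categorical.from_codes(
        codes, categories=list(labels), ordered=True
    )

    rf = fused[reach]
    band_summary = accessibility.summarize_population_by_band(
        rf["static_pop"], rf["band"], rf["urban_class"]
    )

    months = sorted(observations["month"].unique())
    strata = ratios.hour_daytype_strata() + ratios.month_strata(months)
    ratio_tab = ratios.ratio_table(fused, observations, strata)

    catchments = accessibility.derive_catchments(assignments)
    summaries: dict[tuple[int, int], pd.DataFrame] = {}
    moran_res: dict[tuple[int, int], spatial.MoranResult | None] = {}
    anova_res: dict[tuple[int, int], spatial.AnovaResult | None] = {}
    tukey_res: dict[tuple[int, int], list[spatial.TukeyPair]] = {}
    for month, hour in config.catchment_strata:
        if month not in months:
            continue
        st = ratios.Stratum(month=month, hour=hour)
        summ = ratios.catchment_summaries(fused, catchments, eds, observations, st)
        summaries[(month, hour)] = summ
        centroids = accessibility.catchment_centroids(catchments, fused)
        merged = summ.merge(centroids, on="ed_id")
        pts = merged[["x", "y"]].to_numpy()
        values = merged["diff_pct"].to_numpy()
        try:
            weights = spatial.inverse_distance_weights(pts)
            moran_res[(month, hour)] = spatial.morans_i(
                values, weights, config.n_permutations, config.seed
            )
        except ValueError as exc:
            logger.info("Moran's I undefined at month=%d hour=%d: %s", month, hour, exc)
            moran_res[(month, hour)] = None
        groups = {
            lvl: grp["diff_pct"].tolist() for lvl, grp in summ.groupby("level")
        }
        try:
            anova_res[(month, hour)] = spatial.one_way_anova(groups)
            tukey_res[(month, hour)] = spatial.tukey_hsd(groups)
        except ValueError as exc:
            logger.info("ANOVA skipped at month=%d hour=%d: %s", month, hour, exc)
            anova_res[(month, hour)] = None
            tukey_res[(month, hour)] = []

    cfg_dict = {
        "simulate": config.simulate.to_dict() if config.simulate else None,
        "max_snap_m": config.max_snap_m,
        "band_edges": list(config.band_edges),
        "catchment_strata": [list(s) for s in config.catchment_strata],
        "n_permutations": config.n_permutations,
        "seed": config.seed,
    }
    manifest = {
        "package": "dynaccess",
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_fused_cells": int(len(fused)),
        "n_omitted_cells": n_omitted,
        "omitted_pct": round(100.0 * n_omitted / len(fused), 3),
        "n_eds": int(len(eds)),
        "n_observations": int(len(observations)),
    }

    result = PipelineResult(
        fused=fused,
        eds=eds,
        band_summary=band_summary,
        ratio_table=ratio_tab,
        catchment_summaries=summaries,
        moran=moran_res,
        anova=anova_res,
        tukey=tukey_res,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, inputs, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, inputs: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_grid_geojson(inputs["static"], outdir / "static_grid.geojson")
    io.write_grid_geojson(inputs["dynamic_obs"][0], outdir / "dynamic_grid.geojson")
    io.write_roads_geojson(inputs["segments"], outdir / "roads.geojson")
    io.write_eds_geojson(inputs["eds"], outdir / "eds.geojson")
    io.write_observations_csv(inputs["dynamic_obs"][1], outdir / "observations.csv")
    io.write_classes_csv(inputs["classes"], outdir / "classes.csv")

    fused_out = result.fused.drop(columns=["band"]).assign(
        band=result.fused["band"].astype(str)
    )
    io.write_grid_geojson(fused_out, outdir / "fused_grid.geojson")
    result.band_summary.sums.to_csv(outdir / "band_sums.csv")
    result.band_summary.shares_pct.to_csv(outdir / "band_shares_pct.csv")
    result.ratio_table.to_csv(outdir / "ratios.csv", index=False)
    for (month, hour), summ in result.catchment_summaries.items():
        summ.to_csv(outdir / f"catchments_m{month:02d}_h{hour:02d}.csv", index=False)

    stats_rows = []
    for key, mres in result.moran.items():
        row: dict = {"month": key[0], "hour": key[1]}
        if mres is not None:
            row.update(
                moran_i=mres.I,
                moran_expected=mres.expected,
                moran_z=mres.z,
                moran_p_analytic=mres.p_analytic,
                moran_p_permutation=mres.p_permutation,
                threshold_m=mres.threshold_m,
                seed=mres.seed,
            )
        ares = result.anova.get(key)
        if ares is not None:
            row.update(
                anova_f=ares.F, df_between=ares.df_between,
                df_within=ares.df_within, anova_p=ares.p,
            )
        stats_rows.append(row)
    pd.DataFrame(stats_rows).to_csv(outdir / "moran_anova.csv", index=False)
    tukey_rows = [
        {
            "month": key[0], "hour": key[1],
            "group_a": t.group_a, "group_b": t.group_b,
            "difference": t.difference, "half_width": t.half_width,
            "p_adjusted": t.p_adjusted,
        }
        for key, pairs in result.tukey.items()
        for t in pairs
    ]
    pd.DataFrame(tukey_rows).to_csv(outdir / "tukey.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
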