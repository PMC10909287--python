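"""Readers and writers for the pipeline's standard formats.

All geometry is exchanged as GeoJSON in projected planar metres (a
projected CRS is assumed and recorded verbatim, never reprojected);
tables are tidy CSV.  Readers validate schemas up front and name the
offending feature or line in errors, so a malformed input fails at the
boundary rather than deep in the analysis.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from shapely.geometry import box, mapping, shape

from .roads import RoadSegment

logger = logging.getLogger(__name__)

__all__ = [
    "write_grid_geojson",
    "read_grid_geojson",
    "write_roads_geojson",
    "read_roads_geojson",
    "write_eds_geojson",
    "read_eds_geojson",
    "write_observations_csv",
    "read_observations_csv",
    "write_classes_csv",
    "read_classes_csv",
]

_DAYTYPES = {"weekday", "weekend"}


def _feature_collection(features: list[dict], crs: str | None) -> dict:
    fc: dict = {"type": "FeatureCollection", "features": features}
    if crs:
        fc["crs"] = crs
    return fc


def _load_fc(path) -> dict:
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    if not fc.get("features"):
        logger.warning("%s: empty FeatureCollection", path)
    return fc


# ---------------------------------------------------------------------------
# grids


def write_grid_geojson(grid: pd.DataFrame, path, crs: str = "planar-metres") -> None:
    """Square grid cells as Polygon features with their attributes."""
    extra = [c for c in grid.columns if c not in ("cell_id", "x0", "y0", "size_m")]
    features = []
    for row in grid.itertuples(index=False):
        r = row._asdict()
        geom = box(r["x0"], r["y0"], r["x0"] + r["size_m"], r["y0"] + r["size_m"])
        props = {"cell_id": r["cell_id"], **{c: r[c] for c in extra}}
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    Path(path).write_text(json.dumps(_feature_collection(features, crs)))


def read_grid_geojson(path) -> pd.DataFrame:
    """Read a square-cell grid; validates squareness and populations."""
    fc = _load_fc(path)
    rows = []
    for feat in fc["features"]:
        props = dict(feat.get("properties") or {})
        cid = props.pop("cell_id", None)
        if cid is None:
            raise ValueError(f"{path}: grid feature missing cell_id")
        geom = shape(feat["geometry"])
        x0, y0, x1, y1 = geom.bounds
        if abs((x1 - x0) - (y1 - y0)) > 1e-6 * max(x1 - x0, 1.0):
            raise ValueError(f"{path}: cell {cid!r} is not square")
        pop = props.get("static_pop")
        if pop is not None and float(pop) < 0:
            raise ValueError(f"{path}: cell {cid!r} has negative static_pop")
        rows.append({"cell_id": cid, "x0": x0, "y0": y0, "size_m": x1 - x0, **props})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# roads


def write_roads_geojson(
    segments: list[RoadSegment], path, crs: str = "planar-metres"
) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": [list(c) for c in s.coords]},
            "properties": {"id": s.id, "speed_kmh": s.speed_kmh},
        }
        for s in segments
    ]
    Path(path).write_text(json.dumps(_feature_collection(features, crs)))


def read_roads_geojson(path) -> list[RoadSegment]:
    fc = _load_fc(path)
    segments = []
    for k, feat in enumerate(fc["features"]):
        props = feat.get("properties") or {}
        sid = str(props.get("id", f"feature-{k}"))
        speed = props.get("speed_kmh")
        if speed is None or float(speed) <= 0:
            raise ValueError(f"{path}: road {sid!r} needs positive speed_kmh")
        geom = feat["geometry"]
        if geom["type"] != "LineString":
            raise ValueError(f"{path}: road {sid!r} is not a LineString")
        seg = RoadSegment(
            id=sid,
            coords=[tuple(map(float, c)) for c in geom["coordinates"]],
            speed_kmh=float(speed),
        )
        seg.validate()
        segments.append(seg)
    return segments


# ---------------------------------------------------------------------------
# EDs


def write_eds_geojson(eds: pd.DataFrame, path, crs: str = "planar-metres") -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
            "properties": {"ed_id": row.ed_id, "level": int(row.level)},
        }
        for row in eds.itertuples(index=False)
    ]
    Path(path).write_text(json.dumps(_feature_collection(features, crs)))


def read_eds_geojson(path) -> pd.DataFrame:
    fc = _load_fc(path)
    rows = []
    for k, feat in enumerate(fc["features"]):
        props = feat.get("properties") or {}
        ed_id = props.get("ed_id", f"feature-{k}")
        level = props.get("level")
        if level not in (1, 2, 3):
            raise ValueError(f"{path}: ED {ed_id!r} has invalid level {level!r}")
        x, y = feat["geometry"]["coordinates"]
        rows.append({"ed_id": str(ed_id), "x": float(x), "y": float(y), "level": int(level)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV tables


def write_observations_csv(observations: pd.DataFrame, path) -> None:
    observations.to_csv(path, index=False)


def read_observations_csv(path, dynamic_grid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format hourly counts ``cell_id,month,daytype,hour,count``.

    Validates ranges row by row (reported with 1-based data line
    numbers) and, when the dynamic grid is supplied, membership of every
    cell id.
    """
    obs = pd.read_csv(path)
    required = ["cell_id", "month", "daytype", "hour", "count"]
    missing = [c for c in required if c not in obs.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for line, row in enumerate(obs.itertuples(index=False), start=2):
        if not 1 <= row.month <= 12:
            raise ValueError(f"{path}:{line}: month {row.month} out of range")
        if row.daytype not in _DAYTYPES:
            raise ValueError(f"{path}:{line}: unknown daytype {row.daytype!r}")
        if not 0 <= row.hour <= 23:
            raise ValueError(f"{path}:{line}: hour {row.hour} out of range")
        if not row.count >= 0:
            raise ValueError(f"{path}:{line}: negative count {row.count}")
    if dynamic_grid is not None:
        known = set(dynamic_grid["cell_id"])
        unknown = sorted(set(obs["cell_id"]) - known)
        if unknown:
            raise ValueError(f"{path}: unknown cell ids {unknown[:5]}")
    return obs


def write_classes_csv(classes: pd.DataFrame, path) -> None:
    classes[["cell_id", "urban_class"]].to_csv(path, index=False)


def read_classes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"cell_id", "urban_class"} <= set(df.columns):
        raise ValueError(f"{path}: needs columns cell_id, urban_class")
    return df
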