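"""Minimal RFC 7946 GeoJSON helpers (WGS84 lon/lat order).

Features are plain dicts written with the stdlib json module; shapely supplies
geometry objects where a representative point must be derived from a polygon.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon, shape

from .kernels import FACILITY_KINDS, FacilityLayer, RoadLayer, TractPoint

__all__ = [
    "write_feature_collection",
    "read_feature_collection",
    "write_tracts_geojson",
    "read_tract_points",
    "read_tract_geometries",
    "write_hazards_geojson",
    "read_hazards_geojson",
]


def write_feature_collection(features: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_feature_collection(path: str | Path) -> list[dict]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    return doc["features"]


def write_tracts_geojson(
    geometries: dict[str, Polygon],
    points: dict[str, tuple[float, float]] | None = None,
    properties: dict[str, dict] | None = None,
    path: str | Path = "tracts.geojson",
) -> Path:
    """Tract polygons with an optional representative point stored as a property."""
    features = []
    for tract_id, geom in geometries.items():
        props = {"tract_id": tract_id}
        if points and tract_id in points:
            lon, lat = points[tract_id]
            props["point_lon"] = lon
            props["point_lat"] = lat
        if properties and tract_id in properties:
            props.update(properties[tract_id])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [list(map(list, geom.exterior.coords))]},
                "properties": props,
            }
        )
    return write_feature_collection(features, path)


def read_tract_geometries(path: str | Path) -> dict[str, Polygon]:
    out = {}
    for f in read_feature_collection(path):
        tid = f["properties"]["tract_id"]
        out[tid] = shape(f["geometry"])
    return out


def read_tract_points(path: str | Path) -> list[TractPoint]:
    """Tract evaluation points: the stored point property if present, else the
    polygon's representative point."""
    points = []
    for f in read_feature_collection(path):
        props = f["properties"]
        tid = props["tract_id"]
        if "point_lon" in props and "point_lat" in props:
            points.append(TractPoint(tid, float(props["point_lon"]), float(props["point_lat"])))
        else:
            geom = shape(f["geometry"])
            p = geom if geom.geom_type == "Point" else geom.representative_point()
            points.append(TractPoint(tid, p.x, p.y))
    return points


def write_hazards_geojson(
    layers: dict[str, FacilityLayer],
    roads: RoadLayer | None,
    path: str | Path,
) -> Path:
    """Facilities as Point features (property ``kind``), roads as LineStrings
    (property ``aadt``)."""
    features: list[dict] = []
    for kind, layer in layers.items():
        for lon, lat in zip(layer.lons, layer.lats):
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(lon), float(lat)]},
                    "properties": {"kind": kind},
                }
            )
    if roads is not None:
        for seg, aadt in zip(roads.segments, roads.aadt):
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "LineString", "coordinates": [list(map(float, v)) for v in seg]},
                    "properties": {"aadt": float(aadt)},
                }
            )
    return write_feature_collection(features, path)


def read_hazards_geojson(path: str | Path) -> tuple[dict[str, FacilityLayer], RoadLayer | None]:
    facilities: dict[str, list[tuple[float, float]]] = {}
    segments: list[np.ndarray] = []
    aadt: list[float] = []
    for f in read_feature_collection(path):
        geom = f["geometry"]
        props = f.get("properties") or {}
        if geom["type"] == "Point":
            kind = props.get("kind")
            if kind not in FACILITY_KINDS:
                raise ValueError(f"{path}: facility feature with unknown kind {kind!r}")
            facilities.setdefault(kind, []).append(tuple(geom["coordinates"]))
        elif geom["type"] == "LineString":
            segments.append(np.asarray(geom["coordinates"], dtype=float))
            aadt.append(float(props.get("aadt", 0.0)))
        else:
            raise ValueError(f"{path}: unsupported geometry type {geom['type']!r}")
    layers = {
        kind: FacilityLayer(kind, np.array([p[0] for p in pts]), np.array([p[1] for p in pts]))
        for kind, pts in facilities.items()
    }
    roads = RoadLayer(segments, np.asarray(aadt)) if segments else None
    return layers, roads
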