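"""Geometric exposure indicators: buffered inverse-distance kernels.

Facility proximity is the count of facilities within the buffer, each weighted
by the reciprocal of its distance — i.e. ``sum(1/d_i)`` over facilities with
``d_i <= radius`` — with a nearest-facility fallback (``1/d_nearest``) when the
buffer is empty, so the score stays continuous as the nearest site crosses the
buffer edge.  Traffic proximity-and-volume is the analogous
``sum(AADT_i / d_i)`` over road segments within 500 m of the tract point.

Distances are great-circle on a sphere of radius 6371.0088 km.  Point-to-road
distance is the exact closest approach to the polyline, computed in a local
equirectangular plane around the tract point (sub-millimetre error at the
sub-kilometre ranges where the kernel has weight).  A distance floor
(0.1 km / 10 m by default) caps the kernel when a hazard sits on top of the
evaluation point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScoringConfig
from .indicators import IndicatorDef, IndicatorTable, default_schema

__all__ = [
    "EARTH_RADIUS_KM",
    "FACILITY_KINDS",
    "FacilityLayer",
    "RoadLayer",
    "TractPoint",
    "HousingCounts",
    "haversine_km",
    "proximity_score",
    "traffic_score",
    "lead_paint_fraction",
    "compute_kernel_indicators",
]

EARTH_RADIUS_KM = 6371.0088

#: facility kind -> indicator column it feeds
FACILITY_KINDS = {
    "TSDF": "proximity_tsdf",
    "RMP": "proximity_rmp",
    "NPL": "proximity_npl",
    "water_discharge": "proximity_water_discharge",
}


@dataclass(frozen=True)
class TractPoint:
    """Representative point at which a tract's kernels are evaluated.

    The methodology does not fix the evaluation geometry (centroid vs
    population-weighted point); callers supply whichever point they trust.
    """

    tract_id: str
    lon: float
    lat: float


@dataclass
class FacilityLayer:
    kind: str
    lons: np.ndarray
    lats: np.ndarray

    def __post_init__(self) -> None:
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        if self.lons.shape != self.lats.shape:
            raise ValueError("lons and lats must have the same length")
        if self.lons.size and (
            np.abs(self.lons).max() > 180.0 or np.abs(self.lats).max() > 90.0
        ):
            raise ValueError("coordinates outside valid lon/lat ranges")

    def __len__(self) -> int:
        return self.lons.size


@dataclass
class RoadLayer:
    """Polyline road segments, each with an annual-average daily traffic count."""

    segments: list[np.ndarray]  # each (k, 2) array of lon/lat vertices, k >= 2
    aadt: np.ndarray  # vehicles/day, one per segment

    def __post_init__(self) -> None:
        self.segments = [np.asarray(s, dtype=float) for s in self.segments]
        self.aadt = np.asarray(self.aadt, dtype=float)
        if len(self.segments) != self.aadt.size:
            raise ValueError("one AADT value per segment required")
        for s in self.segments:
            if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] != 2:
                raise ValueError("each segment needs >= 2 lon/lat vertices")
        if self.aadt.size and self.aadt.min() < 0:
            raise ValueError("AADT must be nonnegative")

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class HousingCounts:
    tract_id: str
    units_pre1960: int
    units_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.units_pre1960 <= self.units_total:
            raise ValueError(
                f"need 0 <= units_pre1960 <= units_total, got {self.units_pre1960}/{self.units_total}"
            )


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (vectorised over either endpoint)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def proximity_score(
    point: TractPoint,
    layer: FacilityLayer,
    radius_km: float = 5.0,
    min_distance_km: float = 0.1,
) -> float:
    """Inverse-distance facility proximity: sum of 1/d over in-buffer sites (1/km).

    Falls back to ``1/d_nearest`` when no facility lies within *radius_km*.
    """
    if len(layer) == 0:
        raise ValueError(f"no facilities in layer {layer.kind!r}")
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    d = haversine_km(point.lon, point.lat, layer.lons, layer.lats)
    d = np.maximum(d, min_distance_km)
    inside = d <= radius_km
    if inside.any():
        return float(np.sum(1.0 / d[inside]))
    return float(1.0 / d.min())


def _local_plane_m(lon0: float, lat0: float, lons: np.ndarray, lats: np.ndarray):
    """Equirectangular projection (metres) centred on (lon0, lat0)."""
    r_m = EARTH_RADIUS_KM * 1000.0
    x = np.radians(lons - lon0) * math.cos(math.radians(lat0)) * r_m
    y = np.radians(lats - lat0) * r_m
    return x, y


def _point_to_polyline_m(point: TractPoint, vertices: np.ndarray) -> float:
    """Closest approach (m) from the tract point to one polyline."""
    x, y = _local_plane_m(point.lon, point.lat, vertices[:, 0], vertices[:, 1])
    ax, ay = x[:-1], y[:-1]
    bx, by = x[1:], y[1:]
    dx, dy = bx - ax, by - ay
    seg_len2 = dx * dx + dy * dy
    # parameter of the foot of the perpendicular from the origin, clamped to the edge
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(seg_len2 > 0, -(ax * dx + ay * dy) / seg_len2, 0.0)
    t = np.clip(t, 0.0, 1.0)
    cx, cy = ax + t * dx, ay + t * dy
    return float(np.sqrt(cx * cx + cy * cy).min())


def traffic_score(
    point: TractPoint,
    roads: RoadLayer,
    radius_m: float = 500.0,
    min_distance_m: float = 10.0,
) -> float:
    """Traffic proximity and volume: sum of AADT/d over in-buffer road segments.

    Units are vehicles/day per metre; nearest-segment fallback mirrors
    :func:`proximity_score`.
    """
    if len(roads) == 0:
        raise ValueError("no road segments in layer")
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    d = np.array([_point_to_polyline_m(point, s) for s in roads.segments])
    d = np.maximum(d, min_distance_m)
    inside = d <= radius_m
    if inside.any():
        return float(np.sum(roads.aadt[inside] / d[inside]))
    i = int(np.argmin(d))
    return float(roads.aadt[i] / d[i])


def lead_paint_fraction(h: HousingCounts) -> float:
    """Fraction of housing units built before 1960 (lead-paint likelihood proxy).

    A tract with no housing has no defined fraction: returns NaN, never 0.
    """
    if h.units_total == 0:
        return float("nan")
    return h.units_pre1960 / h.units_total


def compute_kernel_indicators(
    tracts: list[TractPoint],
    layers: dict[str, FacilityLayer] | None = None,
    roads: RoadLayer | None = None,
    housing: list[HousingCounts] | None = None,
    config: ScoringConfig | None = None,
    schema: list[IndicatorDef] | None = None,
) -> IndicatorTable:
    """Evaluate every geometry-derived indicator at each tract point.

    Any absent hazard layer leaves its column entirely missing (NaN), never
    zero — absence of data is not absence of hazard.
    """
    config = config or ScoringConfig()
    layers = layers or {}
    index = pd.Index([t.tract_id for t in tracts], name="tract_id")
    out = pd.DataFrame(index=index, dtype=float)
    for kind, column in FACILITY_KINDS.items():
        layer = layers.get(kind)
        if layer is None or len(layer) == 0:
            out[column] = np.nan
            continue
        out[column] = [
            proximity_score(t, layer, config.radius_km, config.min_distance_km) for t in tracts
        ]
    if roads is not None and len(roads) > 0:
        out["traffic"] = [traffic_score(t, roads, config.radius_m, config.min_distance_m) for t in tracts]
    else:
        out["traffic"] = np.nan
    if housing:
        frac = {h.tract_id: lead_paint_fraction(h) for h in housing}
        out["lead_paint"] = [frac.get(t, np.nan) for t in index]
    else:
        out["lead_paint"] = np.nan
    return IndicatorTable(out, schema or default_schema())
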