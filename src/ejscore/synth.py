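"""Seed-reproducible synthetic counties with a planted severity gradient.

A synthetic region is a square grid of tract cells over which a latent
*severity* field ``s`` in [0, 1] is drawn.  The field is spatially smooth
(linear gradient plus Gaussian-filtered noise, rank-uniformised): vulnerability
clusters in real regions, and spatial autocorrelation is what lets biased
facility siting show up in the proximity kernels of the *same* tracts whose
demographic indicators are elevated.

Every directly-input indicator is a monotone link of the severity:
logit-normal for proportions, lognormal for concentrations and rates, with
per-indicator location/scale set to plausible county-scale magnitudes.  The
six geometry-derived indicators are *not* synthesised — facilities and roads
are sited with probability proportional to ``exp(siting_bias * s)`` and the
kernels of :mod:`ejscore.kernels` are evaluated on the resulting layers, so
the generator exercises the same code path as real hazard data.

All randomness flows from one ``numpy.random.default_rng(seed)``; the fixture
is a deterministic function of its config.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from types import MappingProxyType

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit
from scipy.stats import norm, rankdata
from shapely.geometry import Polygon

from .geojson import write_hazards_geojson, write_tracts_geojson
from .indicators import IndicatorTable, default_schema
from .kernels import (
    FACILITY_KINDS,
    FacilityLayer,
    HousingCounts,
    RoadLayer,
    TractPoint,
    compute_kernel_indicators,
)

__all__ = ["RegionConfig", "RegionFixture", "generate_region", "bladensburg_like_demo"]

KM_PER_DEG_LAT = 111.19492664455873  # 2*pi*R/360 on the scoring sphere

DEFAULT_FACILITIES = MappingProxyType({"TSDF": 12, "RMP": 15, "NPL": 6, "water_discharge": 18})

# indicator -> (link family, location on link scale, scale multiplier)
_LINKS = {
    "nata_cancer_risk": ("log", math.log(30.0), 0.25),
    "nata_resp_hi": ("log", math.log(0.4), 0.30),
    "nata_dpm": ("log", math.log(0.6), 0.40),
    "pm25": ("log", math.log(9.0), 0.08),
    "ozone": ("log", math.log(42.0), 0.05),
    "watershed_failure": ("logit", logit(0.25), 0.80),
    "asthma_er_discharges": ("log", math.log(60.0), 0.40),
    "mi_discharges": ("log", math.log(25.0), 0.30),
    "low_birth_weight": ("logit", logit(0.08), 0.30),
    "pct_nonwhite": ("logit", logit(0.35), 1.20),
    "pct_low_income": ("logit", logit(0.25), 0.80),
    "pct_less_hs": ("logit", logit(0.12), 0.70),
    "pct_linguistic_isolation": ("logit", logit(0.04), 0.90),
    "pct_under_5": ("logit", logit(0.06), 0.20),
    "pct_over_64": ("logit", logit(0.14), 0.25),
    "pct_unemployed": ("logit", logit(0.07), 0.50),
}
_LEAD_PAINT_LINK = (logit(0.30), 1.0)


@dataclass(frozen=True)
class RegionConfig:
    """Stated world of one synthetic county group.

    ``severity_gradient`` scales how strongly every indicator tracks the latent
    severity (0 = pure noise, 1 = severity-dominated); ``noise_sigma`` is the
    standard deviation of the per-indicator Gaussian noise on the latent
    (standard-normal) scale; ``siting_bias`` is the log-odds slope of facility
    placement toward high-severity tracts (0 = uniform siting).
    """

    n_tracts: int = 100
    grid_shape: tuple[int, int] | None = None
    n_facilities: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_FACILITIES))
    n_road_segments: int = 40
    severity_gradient: float = 0.8
    noise_sigma: float = 0.1
    siting_bias: float = 2.0
    seed: int = 0
    n_counties: int = 2
    origin: tuple[float, float] = (-76.95, 38.94)  # lon/lat of grid SW corner
    cell_deg: float = 0.01  # ~1.1 km cells
    focus_tract_index: int | None = None  # severity peak planted on this tract

    def __post_init__(self) -> None:
        if self.n_tracts < 4:
            raise ValueError("n_tracts must be >= 4")
        if any(v < 0 for v in self.n_facilities.values()) or self.n_road_segments < 0:
            raise ValueError("hazard counts must be >= 0")
        if not 0.0 <= self.severity_gradient <= 1.0:
            raise ValueError("severity_gradient must be in [0, 1]")
        if self.noise_sigma < 0 or self.siting_bias < 0:
            raise ValueError("noise_sigma and siting_bias must be >= 0")
        if self.n_counties < 1:
            raise ValueError("n_counties must be >= 1")

    def shape(self) -> tuple[int, int]:
        if self.grid_shape is not None:
            nrows, ncols = self.grid_shape
            if nrows * ncols < self.n_tracts:
                raise ValueError("grid_shape too small for n_tracts")
            return nrows, ncols
        nrows = max(2, int(math.floor(math.sqrt(self.n_tracts))))
        ncols = int(math.ceil(self.n_tracts / nrows))
        return nrows, ncols


@dataclass
class RegionFixture:
    """A generated region: geometry, hazards, indicators and the ground truth."""

    config: RegionConfig
    table: IndicatorTable
    points: list[TractPoint]
    geometries: dict[str, Polygon]
    facility_layers: dict[str, FacilityLayer]
    roads: RoadLayer | None
    housing: list[HousingCounts]
    severity: pd.Series  # latent ground truth s in [0, 1], indexed by tract_id
    focus_tract_id: str | None = None

    def export(self, directory: str | Path) -> dict[str, Path]:
        """Write the fixture in the same CSV/GeoJSON formats the pipeline reads."""
        from .indicators import write_indicator_table

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "indicators": write_indicator_table(self.table, directory / "indicators.csv"),
            "tracts": write_tracts_geojson(
                self.geometries,
                {p.tract_id: (p.lon, p.lat) for p in self.points},
                path=directory / "tracts.geojson",
            ),
            "hazards": write_hazards_geojson(
                self.facility_layers, self.roads, directory / "hazards.geojson"
            ),
        }
        truth = directory / "severity.csv"
        self.severity.rename("severity").to_csv(truth, index_label="tract_id")
        paths["severity"] = truth
        return paths


def _severity_field(
    rng: np.random.Generator,
    nrows: int,
    ncols: int,
    n: int,
    focus: int | None = None,
) -> np.ndarray:
    """Smooth latent field, rank-uniformised to s in (0, 1).

    When *focus* is given, a Gaussian severity peak (2-cell width) is planted
    on that tract so it is the regional maximum and its whole neighbourhood is
    elevated — hazard siting then concentrates around it, as in a genuinely
    overburdened locale.
    """
    noise = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=1.5)
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    trend = (rr / max(nrows - 1, 1) + cc / max(ncols - 1, 1)) / 2.0
    sd = noise.std()
    field = trend + 0.8 * (noise / sd if sd > 0 else noise)
    if focus is not None:
        r0, c0 = divmod(focus, ncols)
        spread = field.max() - field.min()
        field += 1.5 * spread * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * 2.0**2))
    flat = field.ravel()[:n]
    return (rankdata(flat, method="ordinal") - 0.5) / n


def generate_region(cfg: RegionConfig) -> RegionFixture:
    """Generate one region; bit-identical for equal configs."""
    rng = np.random.default_rng(cfg.seed)
    nrows, ncols = cfg.shape()
    n = cfg.n_tracts
    lon0, lat0 = cfg.origin
    cell = cfg.cell_deg

    rows, cols = np.divmod(np.arange(n), ncols)
    county_idx = (cols * cfg.n_counties) // ncols
    county_ids = [f"{24001 + 2 * int(c):05d}" for c in county_idx]
    tract_ids = [f"{county_ids[i]}{i + 1:06d}" for i in range(n)]

    s = _severity_field(rng, nrows, ncols, n, cfg.focus_tract_index)

    # geometry: axis-aligned square cells; evaluation point jittered off-centre
    geometries: dict[str, Polygon] = {}
    points: list[TractPoint] = []
    cell_lon = lon0 + cols * cell
    cell_lat = lat0 + rows * cell
    jitter = rng.uniform(0.25, 0.75, size=(n, 2))
    for i, tid in enumerate(tract_ids):
        x0, y0 = cell_lon[i], cell_lat[i]
        geometries[tid] = Polygon(
            [(x0, y0), (x0 + cell, y0), (x0 + cell, y0 + cell), (x0, y0 + cell)]
        )
        points.append(TractPoint(tid, x0 + jitter[i, 0] * cell, y0 + jitter[i, 1] * cell))

    # directly-input indicators: monotone link of the severity latent
    g = cfg.severity_gradient
    z = norm.ppf(s)
    data = {}
    for ind, (family, mu, scale) in _LINKS.items():
        t = g * z + cfg.noise_sigma * rng.standard_normal(n)
        data[ind] = np.exp(mu + scale * t) if family == "log" else expit(mu + scale * t)
    # housing stock for the lead-paint kernel
    totals = rng.integers(800, 3000, size=n)
    lp_mu, lp_scale = _LEAD_PAINT_LINK
    lp_t = g * z + cfg.noise_sigma * rng.standard_normal(n)
    pre1960 = np.minimum(np.round(expit(lp_mu + lp_scale * lp_t) * totals), totals).astype(int)
    housing = [HousingCounts(tid, int(p), int(tot)) for tid, p, tot in zip(tract_ids, pre1960, totals)]

    # hazard siting, biased toward high-severity tracts
    probs = np.exp(cfg.siting_bias * s)
    probs = probs / probs.sum()
    layers: dict[str, FacilityLayer] = {}
    for kind in FACILITY_KINDS:
        count = cfg.n_facilities.get(kind, 0)
        if count == 0:
            warnings.warn(f"0 facilities of kind {kind!r}: kernel column will be missing")
            continue
        idx = rng.choice(n, size=count, p=probs)
        u = rng.uniform(0.0, 1.0, size=(count, 2))
        layers[kind] = FacilityLayer(
            kind, cell_lon[idx] + u[:, 0] * cell, cell_lat[idx] + u[:, 1] * cell
        )
    roads = None
    if cfg.n_road_segments > 0:
        idx = rng.choice(n, size=cfg.n_road_segments, p=probs)
        mid_lon = cell_lon[idx] + rng.uniform(0, 1, cfg.n_road_segments) * cell
        mid_lat = cell_lat[idx] + rng.uniform(0, 1, cfg.n_road_segments) * cell
        theta = rng.uniform(0, math.pi, cfg.n_road_segments)
        half_km = rng.uniform(0.5, 2.0, cfg.n_road_segments)
        bend_km = rng.normal(0.0, 0.1, cfg.n_road_segments)
        segments = []
        for k in range(cfg.n_road_segments):
            km2lat = 1.0 / KM_PER_DEG_LAT
            km2lon = 1.0 / (KM_PER_DEG_LAT * math.cos(math.radians(mid_lat[k])))
            ux, uy = math.cos(theta[k]), math.sin(theta[k])
            px, py = -uy, ux  # unit normal, for a slight mid-segment bend
            a = (mid_lon[k] - half_km[k] * ux * km2lon, mid_lat[k] - half_km[k] * uy * km2lat)
            m = (mid_lon[k] + bend_km[k] * px * km2lon, mid_lat[k] + bend_km[k] * py * km2lat)
            b = (mid_lon[k] + half_km[k] * ux * km2lon, mid_lat[k] + half_km[k] * uy * km2lat)
            segments.append(np.array([a, m, b]))
        aadt = np.exp(rng.normal(math.log(20000.0), 0.7, cfg.n_road_segments))
        roads = RoadLayer(segments, aadt)

    kernel_table = compute_kernel_indicators(points, layers, roads, housing)
    df = pd.DataFrame(data, index=pd.Index(tract_ids, name="tract_id"))
    df = pd.concat([df, kernel_table.data], axis=1)
    schema = default_schema()
    order = [d.id for d in schema if d.id in df.columns]
    df = df[order]

    population = pd.Series(rng.integers(1200, 8000, size=n), index=df.index, dtype=float)
    county = pd.Series(county_ids, index=df.index)
    table = IndicatorTable(df, schema, county=county, population=population)
    severity = pd.Series(s, index=df.index, name="severity")
    focus_id = tract_ids[cfg.focus_tract_index] if cfg.focus_tract_index is not None else None
    return RegionFixture(
        cfg, table, points, geometries, layers, roads, housing, severity, focus_id
    )


def bladensburg_like_demo() -> RegionFixture:
    """Fixed 150-tract demo region with one designated high-severity focus tract.

    The focus tract is planted at the maximum of the severity field, so its
    county-reference EJ score lands in the top percentile band — the
    qualitative situation of a small overburdened town inside a large county.
    """
    cfg = RegionConfig(
        n_tracts=150,
        severity_gradient=0.9,
        noise_sigma=0.1,
        siting_bias=2.5,
        seed=42,
        n_counties=3,
    )
    nrows, ncols = cfg.shape()
    # a central cell of the middle county strip
    col = (ncols // 3 + 2 * ncols // 3) // 2
    focus = (nrows // 2) * ncols + col
    cfg = replace(cfg, focus_tract_index=min(focus, cfg.n_tracts - 1))
    return generate_region(cfg)
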