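"""Inverse-distance kernel behaviour against independent brute-force oracles."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from ejscore import (
    FacilityLayer,
    HousingCounts,
    RoadLayer,
    TractPoint,
    compute_kernel_indicators,
    lead_paint_fraction,
    proximity_score,
    traffic_score,
)

R_KM = 6371.0088
KM_PER_DEG_LAT = 2 * math.pi * R_KM / 360.0


def offset_point(lon, lat, east_km, north_km):
    """Place a point a given number of km east/north of (lon, lat)."""
    return (
        lon + east_km / (KM_PER_DEG_LAT * math.cos(math.radians(lat))),
        lat + north_km / KM_PER_DEG_LAT,
    )


# ---------------------------------------------------------------- oracles


def haversine_oracle_km(lon1, lat1, lon2, lat2):
    """Independent scalar great-circle distance (math module, no numpy)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = p2 - p1, math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * R_KM * math.asin(math.sqrt(a))


def proximity_oracle(point, lons, lats, radius_km=5.0, floor_km=0.1):
    ds = [max(haversine_oracle_km(point.lon, point.lat, x, y), floor_km) for x, y in zip(lons, lats)]
    inside = [d for d in ds if d <= radius_km]
    return sum(1.0 / d for d in inside) if inside else 1.0 / min(ds)


def traffic_oracle(point, segments, aadt, radius_m=500.0, floor_m=10.0):
    """Closest-approach via shapely in an equirectangular plane around the point."""
    k = R_KM * 1000.0
    cos0 = math.cos(math.radians(point.lat))

    def project(lon, lat):
        return (math.radians(lon - point.lon) * cos0 * k, math.radians(lat - point.lat) * k)

    origin = Point(0.0, 0.0)
    ds = [max(origin.distance(LineString([project(*v) for v in seg])), floor_m) for seg in segments]
    pairs = [(d, a) for d, a in zip(ds, aadt) if d <= radius_m]
    if pairs:
        return sum(a / d for d, a in pairs)
    i = int(np.argmin(ds))
    return aadt[i] / ds[i]


# ---------------------------------------------------------------- proximity


class TestProximityScore:
    def test_single_facility_at_one_km(self):
        pt = TractPoint("t", -76.9, 38.9)
        lon, lat = offset_point(-76.9, 38.9, 0.0, 1.0)
        layer = FacilityLayer("TSDF", [lon], [lat])
        assert proximity_score(pt, layer) == pytest.approx(1.0, rel=1e-9)

    def test_two_facilities_sum_inverse_distances(self):
        pt = TractPoint("t", -76.9, 38.9)
        p1 = offset_point(-76.9, 38.9, 0.0, 1.0)
        p2 = offset_point(-76.9, 38.9, 2.0, 0.0)
        layer = FacilityLayer("TSDF", [p1[0], p2[0]], [p1[1], p2[1]])
        assert proximity_score(pt, layer) == pytest.approx(1.5, rel=1e-6)

    def test_nearest_facility_fallback_outside_radius(self):
        pt = TractPoint("t", -76.9, 38.9)
        p1 = offset_point(-76.9, 38.9, 0.0, 8.0)
        p2 = offset_point(-76.9, 38.9, 0.0, -6.0)
        layer = FacilityLayer("RMP", [p1[0], p2[0]], [p1[1], p2[1]])
        assert proximity_score(pt, layer) == pytest.approx(1.0 / 6.0, rel=1e-6)

    def test_distance_floor_caps_colocated_facility(self):
        pt = TractPoint("t", -76.9, 38.9)
        layer = FacilityLayer("NPL", [-76.9], [38.9])
        assert proximity_score(pt, layer) == pytest.approx(10.0)  # 1/0.1 km

    def test_empty_layer_is_error(self):
        with pytest.raises(ValueError, match="no facilities"):
            proximity_score(TractPoint("t", 0, 0), FacilityLayer("TSDF", [], []))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pt = TractPoint("t", -76.9, 38.9)
        east, north = rng.uniform(-10, 10, 25), rng.uniform(-10, 10, 25)
        pts = [offset_point(pt.lon, pt.lat, e, n) for e, n in zip(east, north)]
        layer = FacilityLayer("TSDF", [p[0] for p in pts], [p[1] for p in pts])
        got = proximity_score(pt, layer)
        want = proximity_oracle(pt, layer.lons, layer.lats)
        assert got == pytest.approx(want, rel=1e-9)

    def test_adding_in_radius_facility_strictly_increases(self):
        pt = TractPoint("t", -76.9, 38.9)
        base = [offset_point(pt.lon, pt.lat, 1.0, 2.0), offset_point(pt.lon, pt.lat, -3.0, 0.5)]
        layer = FacilityLayer("TSDF", [p[0] for p in base], [p[1] for p in base])
        s0 = proximity_score(pt, layer)
        extra = offset_point(pt.lon, pt.lat, 0.0, 4.0)
        bigger = FacilityLayer("TSDF", [*layer.lons, extra[0]], [*layer.lats, extra[1]])
        assert proximity_score(pt, bigger) > s0

    def test_moving_facility_closer_strictly_increases(self):
        pt = TractPoint("t", -76.9, 38.9)
        far = offset_point(pt.lon, pt.lat, 0.0, 4.0)
        near = offset_point(pt.lon, pt.lat, 0.0, 2.0)
        s_far = proximity_score(pt, FacilityLayer("TSDF", [far[0]], [far[1]]))
        s_near = proximity_score(pt, FacilityLayer("TSDF", [near[0]], [near[1]]))
        assert s_near > s_far

    def test_continuity_across_radius_boundary(self):
        pt = TractPoint("t", -76.9, 38.9)
        just_in = offset_point(pt.lon, pt.lat, 0.0, 5.0 - 1e-7)
        just_out = offset_point(pt.lon, pt.lat, 0.0, 5.0 + 1e-7)
        s_in = proximity_score(pt, FacilityLayer("TSDF", [just_in[0]], [just_in[1]]))
        s_out = proximity_score(pt, FacilityLayer("TSDF", [just_out[0]], [just_out[1]]))
        assert s_in == pytest.approx(s_out, rel=1e-6)

    def test_translation_invariance_near_equator(self):
        rng = np.random.default_rng(4)
        pt = TractPoint("t", 10.0, 0.5)
        pts = [offset_point(pt.lon, pt.lat, e, n) for e, n in rng.uniform(-4, 4, (15, 2))]
        layer = FacilityLayer("TSDF", [p[0] for p in pts], [p[1] for p in pts])
        s0 = proximity_score(pt, layer)
        dlon, dlat = 0.05, 0.05
        shifted = FacilityLayer("TSDF", layer.lons + dlon, layer.lats + dlat)
        s1 = proximity_score(TractPoint("t", pt.lon + dlon, pt.lat + dlat), shifted)
        assert abs(s1 - s0) / s0 < 1e-3


# ---------------------------------------------------------------- traffic


def straight_segment(lon, lat, north_km, half_len_km=2.0):
    a = offset_point(lon, lat, -half_len_km, north_km)
    b = offset_point(lon, lat, half_len_km, north_km)
    return np.array([a, b])


class TestTrafficScore:
    def test_single_segment_100m_aadt_1000(self):
        pt = TractPoint("t", -76.9, 38.9)
        roads = RoadLayer([straight_segment(pt.lon, pt.lat, 0.1)], [1000.0])
        assert traffic_score(pt, roads) == pytest.approx(10.0, rel=1e-6)

    def test_two_segments_sum(self):
        pt = TractPoint("t", -76.9, 38.9)
        roads = RoadLayer(
            [straight_segment(pt.lon, pt.lat, 0.1), straight_segment(pt.lon, pt.lat, -0.25)],
            [1000.0, 1000.0],
        )
        assert traffic_score(pt, roads) == pytest.approx(14.0, rel=1e-6)

    def test_nearest_segment_fallback(self):
        pt = TractPoint("t", -76.9, 38.9)
        roads = RoadLayer(
            [straight_segment(pt.lon, pt.lat, 2.0), straight_segment(pt.lon, pt.lat, -1.0)],
            [500.0, 800.0],
        )
        # nothing within 500 m; nearest is the 1 km segment
        assert traffic_score(pt, roads) == pytest.approx(800.0 / 1000.0, rel=1e-6)

    def test_distance_floor(self):
        pt = TractPoint("t", -76.9, 38.9)
        roads = RoadLayer([straight_segment(pt.lon, pt.lat, 0.0)], [1000.0])
        assert traffic_score(pt, roads) == pytest.approx(100.0)  # 1000 / 10 m floor

    def test_empty_layer_is_error(self):
        with pytest.raises(ValueError, match="no road segments"):
            traffic_score(TractPoint("t", 0, 0), RoadLayer([], []))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_shapely_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        pt = TractPoint("t", -76.9, 38.9)
        segments = []
        for _ in range(10):
            verts = [
                offset_point(pt.lon, pt.lat, e, n)
                for e, n in rng.uniform(-1.5, 1.5, (rng.integers(2, 5), 2))
            ]
            segments.append(np.array(verts))
        aadt = rng.uniform(100, 50000, len(segments))
        got = traffic_score(pt, RoadLayer(segments, aadt))
        want = traffic_oracle(pt, segments, aadt)
        assert got == pytest.approx(want, rel=1e-9)


# ---------------------------------------------------------------- lead paint


@pytest.mark.parametrize(
    "pre, total, expected", [(300, 1000, 0.30), (0, 500, 0.0), (500, 500, 1.0)]
)
def test_lead_paint_fraction(pre, total, expected):
    assert lead_paint_fraction(HousingCounts("t", pre, total)) == expected


def test_lead_paint_no_housing_is_missing_not_zero():
    assert math.isnan(lead_paint_fraction(HousingCounts("t", 0, 0)))


def test_housing_counts_invariant():
    with pytest.raises(ValueError):
        HousingCounts("t", 600, 500)


# ---------------------------------------------------------------- composition


def make_layers(lon, lat, east_km, north_km):
    return {
        kind: FacilityLayer(kind, *zip(*[offset_point(lon, lat, east_km, north_km)]))
        for kind in ("TSDF", "RMP", "NPL", "water_discharge")
    }


class TestComputeKernelIndicators:
    def test_all_layers_present_gives_six_finite_values(self):
        pt = TractPoint("A", -76.9, 38.9)
        layers = make_layers(pt.lon, pt.lat, 1.0, 1.0)
        roads = RoadLayer([straight_segment(pt.lon, pt.lat, 0.1)], [1000.0])
        housing = [HousingCounts("A", 100, 400)]
        t = compute_kernel_indicators([pt], layers, roads, housing)
        assert t.data.shape == (1, 6)
        assert np.isfinite(t.data.to_numpy()).all()

    def test_missing_layer_gives_missing_column_not_zero(self):
        pt = TractPoint("A", -76.9, 38.9)
        layers = make_layers(pt.lon, pt.lat, 1.0, 1.0)
        del layers["RMP"]
        t = compute_kernel_indicators([pt], layers, None, None)
        assert t.data["proximity_rmp"].isna().all()
        assert t.data["traffic"].isna().all()
        assert t.data["lead_paint"].isna().all()
        assert t.data["proximity_tsdf"].notna().all()

    def test_strictly_closer_tract_dominates_every_proximity_column(self):
        # B sits 3 km further from every facility than A along the same ray
        a = TractPoint("A", -76.9, 38.9)
        b_lon, b_lat = offset_point(a.lon, a.lat, 0.0, -3.0)
        b = TractPoint("B", b_lon, b_lat)
        rng = np.random.default_rng(9)
        layers = {}
        for kind in ("TSDF", "RMP", "NPL", "water_discharge"):
            pts = [offset_point(a.lon, a.lat, e, n) for e, n in rng.uniform(1.0, 3.0, (5, 2))]
            layers[kind] = FacilityLayer(kind, [p[0] for p in pts], [p[1] for p in pts])
        t = compute_kernel_indicators([a, b], layers, None, None)
        for col in ("proximity_tsdf", "proximity_rmp", "proximity_npl", "proximity_water_discharge"):
            assert t.data.loc["A", col] > t.data.loc["B", col]
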