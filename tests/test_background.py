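"""Corridor buffers, area-weighted backgrounds, land-use classification."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point, box

import shapely
from sedrisk.background import (
    BufferSpec,
    CoverageError,
    ShortPolylineError,
    area_weighted_background,
    build_upstream_buffer,
    classify_land_use,
    compute_gb_table,
)
from sedrisk.data import LayerMap, SiteGeometry, ValidationError

from conftest import random_grid_layer


def _mc_mean(buffer, layer, analyte, n_points, rng):
    """Point-sampling oracle for the area-weighted mean: uniform points in
    the buffer, each carrying the value of the polygon it falls in."""
    minx, miny, maxx, maxy = buffer.bounds
    xs = rng.uniform(minx, maxx, n_points)
    ys = rng.uniform(miny, maxy, n_points)
    inside = shapely.contains_xy(buffer, xs, ys)
    xs, ys = xs[inside], ys[inside]
    values = np.full(len(xs), np.nan)
    for geom, attrs in layer.features:
        key = f"GB_{analyte}"
        if key not in attrs:
            continue
        hit = shapely.contains_xy(geom, xs, ys)
        values[hit] = attrs[key]
    return np.nanmean(values)


class TestBuildBuffer:
    def test_straight_corridor_area(self, straight_site):
        buf = build_upstream_buffer(straight_site, BufferSpec())
        assert buf.area == pytest.approx(2000 * 500, rel=0.005)

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            BufferSpec(length_m=0)

    def test_short_polyline_error_carries_available_length(self):
        site = SiteGeometry(1, Point(0, 0), LineString([(0, 0), (1200, 0)]))
        with pytest.raises(ShortPolylineError) as err:
            build_upstream_buffer(site, BufferSpec())
        assert err.value.available_m == pytest.approx(1200)

    def test_right_angle_corridor_area_matches_point_sampling(self):
        line = LineString([(0, 0), (1000, 0), (1000, 3000)])
        site = SiteGeometry(1, Point(0, 0), upstream_line=line)
        buf = build_upstream_buffer(site, BufferSpec())
        rng = np.random.default_rng(7)
        minx, miny, maxx, maxy = buf.bounds
        pts = rng.uniform((minx, miny), (maxx, maxy), size=(200_000, 2))
        frac = shapely.contains_xy(buf, pts[:, 0], pts[:, 1]).mean()
        mc_area = frac * (maxx - minx) * (maxy - miny)
        assert buf.area == pytest.approx(mc_area, rel=0.01)
        # corner adds at most a quarter-disc of radius width/2
        assert buf.area < 2000 * 500 + np.pi * 250**2 / 4 + 1.0

    def test_area_monotone_in_spec(self, straight_site):
        base = build_upstream_buffer(straight_site, BufferSpec(2000, 500)).area
        assert build_upstream_buffer(straight_site, BufferSpec(2500, 500)).area >= base
        assert build_upstream_buffer(straight_site, BufferSpec(2000, 600)).area >= base


class TestAreaWeightedBackground:
    def test_single_polygon_identity(self, straight_site, uniform_background_layer):
        buf = build_upstream_buffer(straight_site)
        assert area_weighted_background(buf, uniform_background_layer, "Cd") == pytest.approx(5.49)

    def test_two_class_weighted_mean(self, straight_site):
        # corridor x in [0, 2000]: first quarter value 4, rest value 8
        layer = LayerMap(
            role="background",
            features=[
                (box(0, -250, 500, 250), {"GB_X": 4.0}),
                (box(500, -250, 2000, 250), {"GB_X": 8.0}),
            ],
        )
        buf = build_upstream_buffer(straight_site)
        assert area_weighted_background(buf, layer, "X") == pytest.approx(7.0)

    def test_matches_point_sampling_oracle_on_random_grid(self, straight_site):
        rng = np.random.default_rng(11)
        layer = random_grid_layer(rng)
        buf = build_upstream_buffer(straight_site)
        exact = area_weighted_background(buf, layer, "X")
        mc = _mc_mean(buf, layer, "X", 100_000, rng)
        assert exact == pytest.approx(mc, rel=0.01)
        values = [a["GB_X"] for _, a in layer.features]
        assert min(values) <= exact <= max(values)

    def test_invariant_under_polygon_subdivision(self, straight_site):
        buf = build_upstream_buffer(straight_site)
        one = LayerMap(role="background", features=[(box(-100, -300, 2100, 300), {"GB_X": 3.3})])
        split = LayerMap(
            role="background",
            features=[
                (box(-100, -300, 900, 300), {"GB_X": 3.3}),
                (box(900, -300, 2100, 300), {"GB_X": 3.3}),
            ],
        )
        a = area_weighted_background(buf, one, "X")
        b = area_weighted_background(buf, split, "X")
        assert a == pytest.approx(b, rel=1e-9)

    def test_no_coverage_raises(self, straight_site):
        layer = LayerMap(role="background", features=[(box(50000, 50000, 50010, 50010), {"GB_X": 1.0})])
        buf = build_upstream_buffer(straight_site)
        with pytest.raises(CoverageError):
            area_weighted_background(buf, layer, "X")


class TestComputeGBTable:
    def test_uniform_map_reproduces_value_per_analyte(self, straight_site, uniform_background_layer):
        gb = compute_gb_table([straight_site], uniform_background_layer)
        assert gb.get(1, "Cd") == pytest.approx(5.49)
        assert gb.get(1, "Fe") == pytest.approx(7000.0)

    def test_two_sites_on_distinct_patches(self):
        s1 = SiteGeometry(1, Point(0, 0), LineString([(0, 0), (2500, 0)]))
        s2 = SiteGeometry(2, Point(0, 10000), LineString([(0, 10000), (2500, 10000)]))
        layer = LayerMap(
            role="background",
            features=[
                (box(-500, -500, 3000, 500), {"GB_X": 2.0}),
                (box(-500, 9500, 3000, 10500), {"GB_X": 6.0}),
            ],
        )
        gb = compute_gb_table([s1, s2], layer)
        assert gb.get(1, "X") == pytest.approx(2.0)
        assert gb.get(2, "X") == pytest.approx(6.0)


class TestClassifyLandUse:
    def _layer(self, pieces):
        return LayerMap(role="landcover", features=pieces)

    def test_pure_agricultural(self, straight_site):
        layer = self._layer([(box(-500, -500, 3000, 500), {"clc_group": "agricultural"})])
        buf = build_upstream_buffer(straight_site)
        category, shares = classify_land_use(buf, layer)
        assert category == "agricultural"
        assert shares["agricultural"] == pytest.approx(1.0)

    def test_argmax_category(self, straight_site):
        # x-splits 45% / 40% / 15% of the 2000 m corridor
        layer = self._layer(
            [
                (box(0, -250, 900, 250), {"clc_group": "agricultural"}),
                (box(900, -250, 1700, 250), {"clc_group": "forest_seminatural"}),
                (box(1700, -250, 2000, 250), {"clc_group": "anthropogenic"}),
            ]
        )
        buf = build_upstream_buffer(straight_site)
        category, shares = classify_land_use(buf, layer)
        assert category == "agricultural"
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_exact_tie_goes_to_anthropogenic(self, straight_site):
        layer = self._layer(
            [
                (box(0, -250, 1000, 250), {"clc_group": "agricultural"}),
                (box(1000, -250, 2000, 250), {"clc_group": "anthropogenic"}),
            ]
        )
        buf = build_upstream_buffer(straight_site)
        category, _ = classify_land_use(buf, layer)
        assert category == "anthropogenic"

    def test_water_contributes_share_but_not_category(self, straight_site):
        layer = self._layer(
            [
                (box(0, -250, 800, 250), {"clc_group": "water"}),
                (box(800, -250, 2000, 250), {"clc_group": "forest_seminatural"}),
            ]
        )
        buf = build_upstream_buffer(straight_site)
        category, shares = classify_land_use(buf, layer)
        assert category == "forest"
        assert shares["water"] == pytest.approx(0.4, abs=1e-6)

    def test_no_intersection_raises(self, straight_site):
        layer = self._layer([(box(90000, 90000, 90010, 90010), {"clc_group": "water"})])
        buf = build_upstream_buffer(straight_site)
        with pytest.raises(CoverageError):
            classify_land_use(buf, layer)
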