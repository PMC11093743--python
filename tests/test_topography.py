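"""Coastal exposure geometry: intersections, normals, angles, slopes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wavemorph.errors import NoIntersectionError, UndefinedMeanError
from wavemorph.simulate import CoastGenConfig, gen_coast_bathy
from wavemorph.topography import (
    BathymetryGrid,
    Coastline,
    LocalProjection,
    circle_coast_intersections,
    circular_mean_direction,
    nearshore_slope,
    relative_incidence,
    shore_normal,
    site_topography,
)

LON0, LAT0 = -8.885, 42.0
PROJ = LocalProjection(LON0, LAT0)


def _coast_from_xy(xy):
    lon, lat = PROJ.to_lonlat(np.asarray(xy, float)[:, 0], np.asarray(xy, float)[:, 1])
    return Coastline(np.column_stack([lon, lat]))


def _flat_west_ocean_grid(slope=0.02):
    cfg = CoastGenConfig(center_lon=LON0, center_lat=LAT0, true_slope=slope)
    _, bathy, _ = gen_coast_bathy(cfg)
    return bathy


class TestCircleIntersections:
    def test_straight_ns_coast_through_center(self):
        coast = _coast_from_xy([(0, -2000), (0, 2000)])
        p1, p2 = circle_coast_intersections(coast, LON0, LAT0, 500.0)
        xys = sorted(np.column_stack(PROJ.to_xy(*np.array([p1, p2]).T)).tolist(),
                     key=lambda p: p[1])
        assert xys[0] == pytest.approx([0.0, -500.0], abs=0.5)
        assert xys[1] == pytest.approx([0.0, 500.0], abs=0.5)

    def test_offset_chord_345_triangle(self):
        # N-S line 300 m east of the site: intersections at y = +-400 m
        coast = _coast_from_xy([(300, -2000), (300, 2000)])
        p1, p2 = circle_coast_intersections(coast, LON0, LAT0, 500.0)
        ys = sorted(PROJ.to_xy(*np.array([p1, p2]).T)[1])
        assert ys[0] == pytest.approx(-400.0, abs=0.5)
        assert ys[1] == pytest.approx(400.0, abs=0.5)

    def test_far_coast_raises(self):
        coast = _coast_from_xy([(800, -2000), (800, 2000)])
        with pytest.raises(NoIntersectionError):
            circle_coast_intersections(coast, LON0, LAT0, 500.0)

    def test_multiple_crossings_bracket_nearest_point(self):
        # zig-zag crossing the circle 4 times; kept pair must bracket the
        # along-line point nearest the site
        coast = _coast_from_xy(
            [(-2000, 100), (-300, 100), (-300, 2000), (-250, 2000), (-250, 100), (2000, 100)]
        )
        p1, p2 = circle_coast_intersections(coast, LON0, LAT0, 500.0)
        x1, _ = PROJ.to_xy(*p1)
        x2, _ = PROJ.to_xy(*p2)
        assert min(x1, x2) < 0 < max(x1, x2)


class TestShoreNormal:
    def test_ns_chord_ocean_west(self):
        bathy = _flat_west_ocean_grid()
        inter = (PROJ.to_lonlat(0, 500), PROJ.to_lonlat(0, -500))
        inter = tuple((float(a), float(b)) for a, b in inter)
        assert shore_normal(inter, LON0, LAT0, bathy) == pytest.approx(270.0, abs=0.01)

    def test_ew_chord_ocean_north(self):
        cfg = CoastGenConfig(center_lon=LON0, center_lat=LAT0,
                             orientation=90.0, seaward_bearing=0.0)
        _, bathy, _ = gen_coast_bathy(cfg)
        inter = (PROJ.to_lonlat(-500, 0), PROJ.to_lonlat(500, 0))
        inter = tuple((float(a), float(b)) for a, b in inter)
        assert shore_normal(inter, LON0, LAT0, bathy) == pytest.approx(0.0, abs=0.01)

    def test_diagonal_chord_ocean_southeast(self):
        cfg = CoastGenConfig(center_lon=LON0, center_lat=LAT0,
                             orientation=45.0, seaward_bearing=135.0)
        _, bathy, _ = gen_coast_bathy(cfg)
        d = 500 / np.sqrt(2)
        inter = (PROJ.to_lonlat(-d, -d), PROJ.to_lonlat(d, d))
        inter = tuple((float(a), float(b)) for a, b in inter)
        assert shore_normal(inter, LON0, LAT0, bathy) == pytest.approx(135.0, abs=0.01)


class TestCircularMean:
    @pytest.mark.parametrize(
        "dirs, expected",
        [((350.0, 10.0), 0.0), ((90.0,), 90.0), ((0.0, 90.0), 45.0)],
    )
    def test_examples(self, dirs, expected):
        assert circular_mean_direction(dirs) == pytest.approx(expected, abs=1e-9)

    def test_cancelling_directions_raise(self):
        with pytest.raises(UndefinedMeanError):
            circular_mean_direction([0.0, 180.0])


class TestRelativeIncidence:
    @pytest.mark.parametrize(
        "normal, wave, expected",
        [(270.0, 290.0, 20.0), (350.0, 10.0, 20.0), (90.0, 270.0, 180.0)],
    )
    def test_examples(self, normal, wave, expected):
        assert relative_incidence(normal, wave) == pytest.approx(expected)

    @given(st.floats(0, 360), st.floats(0, 360), st.integers(-2, 2), st.integers(-2, 2))
    def test_symmetric_and_periodic(self, a, b, ka, kb):
        base = relative_incidence(a % 360, b % 360)
        assert relative_incidence(b % 360, a % 360) == pytest.approx(base, abs=1e-9)
        assert relative_incidence((a + 360 * ka) % 360, (b + 360 * kb) % 360) == pytest.approx(
            base, abs=1e-9
        )
        assert 0.0 <= base <= 180.0


class TestNearshoreSlope:
    def test_planar_bathymetry_recovers_exact_slope(self):
        bathy = _flat_west_ocean_grid(slope=0.02)
        s = nearshore_slope(bathy, LON0, LAT0, 270.0)
        assert s == pytest.approx(-0.02, abs=1e-6)

    def test_flat_bathymetry_gives_zero(self):
        bathy = BathymetryGrid(np.full((50, 50), 30.0), LON0 - 0.01, LAT0 - 0.01, 4e-4)
        assert nearshore_slope(bathy, LON0, LAT0, 270.0) == pytest.approx(0.0, abs=1e-12)

    def test_steep_slope_in_observed_range(self):
        bathy = _flat_west_ocean_grid(slope=0.1)
        s = nearshore_slope(bathy, LON0, LAT0, 270.0)
        assert s == pytest.approx(-0.1, abs=1e-6)
        assert -0.1 - 1e-6 <= s <= -0.009  # observed field range of slopes

    def test_reversed_normal_flips_sign(self):
        bathy = _flat_west_ocean_grid(slope=0.02)
        seaward = nearshore_slope(bathy, LON0, LAT0, 270.0)
        landward = nearshore_slope(bathy, LON0, LAT0, 90.0)
        assert landward == pytest.approx(-seaward, abs=1e-9)

    def test_translation_invariance(self):
        cfg = CoastGenConfig(center_lon=LON0 + 0.3, center_lat=LAT0 + 0.3, true_slope=0.04)
        _, bathy, _ = gen_coast_bathy(cfg)
        s = nearshore_slope(bathy, LON0 + 0.3, LAT0 + 0.3, 270.0)
        assert s == pytest.approx(-0.04, abs=1e-6)


class TestEndToEndSite:
    def test_ground_truth_alpha_recovery(self):
        coast, bathy, truth = gen_coast_bathy(
            CoastGenConfig(center_lon=LON0, center_lat=LAT0)
        )
        st_ = site_topography("G01", coast, bathy, LON0, LAT0, [270.0, 270.0])
        assert st_.shore_normal == pytest.approx(truth["shore_normal"], abs=0.1)
        assert st_.alpha == pytest.approx(0.0, abs=0.1)
        assert st_.slope == pytest.approx(truth["slope"], abs=1e-5)

    def test_oblique_swell_alpha_20(self):
        coast, bathy, _ = gen_coast_bathy(CoastGenConfig(center_lon=LON0, center_lat=LAT0))
        st_ = site_topography("G02", coast, bathy, LON0, LAT0, [290.0])
        assert st_.alpha == pytest.approx(20.0, abs=0.1)
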