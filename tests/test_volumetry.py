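"""Geometry core: shoelace areas, trapezoid compartments, extrusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respivol.errors import GeometryError, ParameterError
from respivol.imaging import LANDMARKS, MarkerSet
from respivol.volumetry import (
    COMPARTMENTS,
    CompartmentAreas,
    CompartmentVolumes,
    build_compartments,
    compartment_share,
    extrude,
    pair_breath,
    polygon_area,
    variability_percent,
    volumes_from_markers,
)

from conftest import random_markerset


def markers_from_heights(heights, spacing=5.0):
    return MarkerSet(
        coords={
            name: (spacing * i, float(h)) for i, (name, h) in enumerate(zip(LANDMARKS, heights))
        }
    )


class TestPolygonArea:
    @pytest.mark.parametrize(
        "vertices, expected",
        [
            ([(0, 0), (1, 0), (0, 1)], 0.5),
            ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0),
            ([(0, 0), (0, 1), (1, 1), (1, 0)], 1.0),  # orientation-independent
            ([(2, 3), (7, 3), (7, 9), (2, 9)], 30.0),
        ],
    )
    def test_known_polygons(self, vertices, expected):
        assert polygon_area(vertices) == pytest.approx(expected)

    def test_monte_carlo_oracle_convex_octagon(self):
        """Shoelace area of a random convex 8-gon matches hit-count area."""
        rng = np.random.default_rng(2024)
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=8))
        # vertices on an ellipse: convex and counter-clockwise
        pts = np.column_stack([4.0 * np.cos(angles), 2.5 * np.sin(angles)])
        area = polygon_area(pts)

        n = 1_000_000
        lo, hi = pts.min(0) - 0.1, pts.max(0) + 0.1
        samples = rng.uniform(lo, hi, size=(n, 2))
        # point-in-polygon by winding of cross products (convex polygon)
        inside = np.ones(n, dtype=bool)
        for i in range(8):
            a, b = pts[i], pts[(i + 1) % 8]
            cross = (b[0] - a[0]) * (samples[:, 1] - a[1]) - (b[1] - a[1]) * (
                samples[:, 0] - a[0]
            )
            inside &= cross >= 0
        mc_area = inside.mean() * np.prod(hi - lo)
        assert area == pytest.approx(mc_area, rel=0.005)

    def test_self_intersecting_bowtie_rejected(self):
        with pytest.raises(GeometryError):
            polygon_area([(0, 0), (1, 1), (1, 0), (0, 1)])

    def test_too_few_vertices_rejected(self):
        with pytest.raises(GeometryError):
            polygon_area([(0, 0), (1, 1)])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_shapely_on_random_quads(self, seed):
        """Independent oracle: shapely agrees on random simple quadrilaterals."""
        from shapely.geometry import Polygon

        rng = np.random.default_rng(seed)
        x1, x2 = np.sort(rng.uniform(0, 10, size=2) + [0, 1])
        y1, y2 = rng.uniform(0.1, 10, size=2)
        quad = [(x1, 0.0), (x1, y1), (x2, y2), (x2, 0.0)]
        assert polygon_area(quad) == pytest.approx(Polygon(quad).area, rel=1e-12)


class TestCompartments:
    def test_flat_profile_gives_rectangles(self, flat_markers):
        areas = build_compartments(flat_markers)
        for name in COMPARTMENTS:
            assert getattr(areas, name) == pytest.approx(50.0)

    def test_trapezoid_rule_by_hand(self):
        """Heights 10,12,11,9,8 cm at 5 cm spacing -> 55, 57.5, 50, 42.5 cm^2."""
        areas = build_compartments(markers_from_heights([10, 12, 11, 9, 8]))
        assert areas.UT == pytest.approx(55.0)
        assert areas.LT == pytest.approx(57.5)
        assert areas.UA == pytest.approx(50.0)
        assert areas.LA == pytest.approx(42.5)

    def test_zero_height_profile_has_zero_area(self):
        areas = build_compartments(markers_from_heights([0, 0, 0, 0, 0]))
        assert all(getattr(areas, name) == 0.0 for name in COMPARTMENTS)

    def test_monotone_in_marker_height(self):
        """Raising one marker strictly increases adjacent areas and the total."""
        base = markers_from_heights([10, 12, 11, 9, 8])
        raised = markers_from_heights([10, 13, 11, 9, 8])
        a0, a1 = build_compartments(base), build_compartments(raised)
        assert a1.UT > a0.UT and a1.LT > a0.LT
        assert a1.UA == a0.UA and a1.LA == a0.LA
        v0 = extrude(a0, 25.5).thoracoabdominal
        v1 = extrude(a1, 25.5).thoracoabdominal
        assert v1 > v0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.floats(0.5, 3.0))
    def test_scale_law_in_height(self, seed, k):
        """Multiplying all heights by k multiplies every area by k."""
        rng = np.random.default_rng(seed)
        ms = random_markerset(rng)
        scaled = MarkerSet(
            coords={name: (x, k * y) for name, (x, y) in ms.coords.items()}
        )
        a, ak = build_compartments(ms), build_compartments(scaled)
        for name in COMPARTMENTS:
            assert getattr(ak, name) == pytest.approx(k * getattr(a, name), rel=1e-9)


class TestExtrusion:
    def test_unit_arithmetic(self):
        areas = CompartmentAreas(UT=100.0, LT=0.0, UA=0.0, LA=0.0)
        assert extrude(areas, 25.5).UT == pytest.approx(2.55)

    def test_linear_in_depth(self):
        areas = CompartmentAreas(UT=120.0, LT=80.0, UA=50.0, LA=60.0)
        v1, v2 = extrude(areas, 20.0), extrude(areas, 40.0)
        for name in ("UT", "LT", "TT", "UA", "LA", "TA", "thoracoabdominal"):
            assert getattr(v2, name) == pytest.approx(2 * getattr(v1, name))

    def test_zero_areas_zero_volumes(self):
        v = extrude(CompartmentAreas(0, 0, 0, 0), 25.5)
        assert v.thoracoabdominal == 0.0

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ParameterError):
            extrude(CompartmentAreas(1, 1, 1, 1), 0.0)

    def test_additive_totals_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            v = volumes_from_markers(random_markerset(rng), float(rng.uniform(20, 30)))
            assert abs(v.TT - (v.UT + v.LT)) <= 1e-9
            assert abs(v.TA - (v.UA + v.LA)) <= 1e-9
            assert abs(v.thoracoabdominal - (v.TT + v.TA)) <= 1e-9

    def test_rasterization_oracle(self):
        """Trapezoid + extrusion agrees with brute-force pixel rasterization.

        The profile polygon is sampled on a fine grid (0.02 cm cells); the
        occupied-cell area times depth must match within 0.5% on random
        marker sets.
        """
        rng = np.random.default_rng(77)
        for _ in range(50):
            ms = random_markerset(rng)
            depth = float(rng.uniform(21.5, 29.5))
            analytic = volumes_from_markers(ms, depth).thoracoabdominal

            pts = ms.as_array()
            cell = 0.02
            xs = np.arange(pts[0, 0], pts[-1, 0], cell) + cell / 2
            profile = np.interp(xs, pts[:, 0], pts[:, 1])
            ymax = pts[:, 1].max()
            ys = np.arange(0, ymax, cell) + cell / 2
            inside = ys[None, :] < profile[:, None]
            raster_area = inside.sum() * cell * cell
            raster_vol = raster_area * depth / 1000.0
            assert analytic == pytest.approx(raster_vol, rel=0.005)


class TestBreathMetrics:
    def test_mobility_from_cohort_totals(self):
        exp = CompartmentVolumes.from_compartments(7.32, 5.90, 2.56, 3.56)
        insp = CompartmentVolumes.from_compartments(8.41, 7.65, 3.16, 3.86)
        pair = pair_breath(exp, insp)
        assert pair.mobility == pytest.approx(
            insp.thoracoabdominal - exp.thoracoabdominal, abs=1e-12
        )
        assert pair.mobility == pytest.approx(3.74, abs=1e-9)

    def test_identical_phases_zero_mobility(self):
        v = CompartmentVolumes.from_compartments(5, 4, 2, 3)
        assert pair_breath(v, v).mobility == 0.0

    def test_negative_mobility_warned_not_raised(self, caplog):
        big = CompartmentVolumes.from_compartments(8, 6, 3, 4)
        small = CompartmentVolumes.from_compartments(7, 5, 2, 3)
        with caplog.at_level("WARNING"):
            pair = pair_breath(big, small)
        assert pair.mobility < 0
        assert "negative mobility" in caplog.text

    @pytest.mark.parametrize(
        "exp, insp, expected",
        [(7.32, 8.41, 14.9), (3.56, 3.86, 8.4), (5.0, 5.0, 0.0)],
    )
    def test_variability_percent(self, exp, insp, expected):
        assert variability_percent(exp, insp) == expected

    def test_variability_requires_positive_expiration(self):
        with pytest.raises(ParameterError):
            variability_percent(0.0, 1.0)

    def test_share_symmetry_and_edge(self):
        even = CompartmentVolumes.from_compartments(4, 4, 4, 4)
        assert compartment_share(even) == (50.0, 50.0)
        thorax_only = CompartmentVolumes.from_compartments(4, 4, 0, 0)
        assert compartment_share(thorax_only) == (100.0, 0.0)

    def test_share_rejects_zero_total(self):
        with pytest.raises(ParameterError):
            compartment_share(CompartmentVolumes.from_compartments(0, 0, 0, 0))
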