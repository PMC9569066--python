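"""Sector partitions: macular quadrants, peripapillary annulus, laterality
naming and physical-scale arithmetic."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from octaquant.geometry import (
    GeometryError,
    RingSpec,
    ScaleSpec,
    macular_quadrants,
    map_laterality,
    mm_per_px,
    ring_sectors,
)
from octaquant.image_io import Eye


def quadrant_oracle(frame_px):
    """Independent point-in-triangle assignment of every pixel center.

    The frame square is split by its diagonals into four triangles with a
    common apex at the frame center; membership is tested geometrically with
    shapely, checking top, bottom, left, right in that precedence order
    (diagonal pixels go to top/bottom).
    """
    n = frame_px
    lo, hi = -0.5, n - 0.5
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    tris = {
        "top": Polygon([(lo, lo), (lo, hi), center]),       # (row, col) vertices
        "bottom": Polygon([(hi, lo), (hi, hi), center]),
        "left": Polygon([(lo, lo), (hi, lo), center]),
        "right": Polygon([(lo, hi), (hi, hi), center]),
    }
    out = {}
    for r in range(n):
        for c in range(n):
            p = Point(r, c)
            for name in ("top", "bottom", "left", "right"):
                if tris[name].covers(p):
                    out[(r, c)] = name
                    break
    return out


class TestMacularQuadrants:
    def test_matches_point_in_triangle_oracle_on_small_frames(self):
        for n in (4, 5, 8):
            sectors = macular_quadrants(n)
            oracle = quadrant_oracle(n)
            for (r, c), name in oracle.items():
                assert sectors.names[sectors.labels[r, c]] == name, (n, r, c)

    def test_example_pixels_on_4px_frame(self):
        sectors = macular_quadrants(4)
        assert sectors.names[sectors.labels[0, 1]] == "top"
        assert sectors.names[sectors.labels[3, 2]] == "bottom"

    def test_partition_covers_every_pixel_exactly_once(self):
        sectors = macular_quadrants(962)
        assert (sectors.labels > 0).all()
        total = sum(int((sectors.labels == i).sum()) for i in sectors.names)
        assert total == 962 * 962

    def test_reflection_symmetric_counts(self):
        sectors = macular_quadrants(962)
        counts = {name: int(sectors.sector_mask(name).sum()) for name in
                  ("top", "bottom", "left", "right")}
        assert counts["top"] == counts["bottom"]
        assert counts["left"] == counts["right"]

    def test_180_rotation_swaps_opposite_quadrants(self):
        sectors = macular_quadrants(250)
        for a, b in (("top", "bottom"), ("left", "right")):
            np.testing.assert_array_equal(
                np.rot90(sectors.sector_mask(a), 2), sectors.sector_mask(b)
            )

    def test_tiny_frame_raises(self):
        with pytest.raises(GeometryError):
            macular_quadrants(1)


@pytest.fixture(scope="module")
def default_ring_od():
    scale = ScaleSpec(fov_deg=15, frame_px=938)
    return ring_sectors(RingSpec(), scale, 938, Eye.OD), scale


class TestRingSectors:
    def test_center_pixel_is_outside_the_annulus(self, default_ring_od):
        sectors, _ = default_ring_od
        assert sectors.labels[468, 468] == 0
        assert sectors.labels[469, 469] == 0

    def test_od_due_left_mid_annulus_is_temporal(self, default_ring_od):
        sectors, scale = default_ring_od
        spec = RingSpec()
        r_mid = (spec.inner_diameter_mm + spec.outer_diameter_mm) / 4 / scale.mm_per_px
        c = (938 - 1) / 2.0
        row, col = int(round(c)), int(round(c - r_mid))
        assert sectors.names[sectors.labels[row, col]] == "temporal"

    def test_os_due_left_mid_annulus_is_nasal(self):
        scale = ScaleSpec(fov_deg=15, frame_px=938)
        sectors = ring_sectors(RingSpec(), scale, 938, Eye.OS)
        c = (938 - 1) / 2.0
        r_mid = (1.7 + 3.4) / 4 / scale.mm_per_px
        assert sectors.names[sectors.labels[int(round(c)), int(round(c - r_mid))]] == "nasal"

    def test_sector_pixel_fractions_match_angular_widths(self, default_ring_od):
        sectors, _ = default_ring_od
        ring_total = int(sectors.union_mask().sum())
        widths = {"superior": 80, "inferior": 80, "nasal": 110, "temporal": 90}
        for name, deg in widths.items():
            frac = sectors.sector_mask(name).sum() / ring_total
            assert frac == pytest.approx(deg / 360.0, abs=0.01)

    def test_annulus_pixel_area_matches_analytic(self, default_ring_od):
        sectors, scale = default_ring_od
        s = scale.mm_per_px
        measured = int(sectors.union_mask().sum()) * s * s
        expected = math.pi * ((3.4 / 2) ** 2 - (1.7 / 2) ** 2)
        assert measured == pytest.approx(expected, rel=0.01)

    def test_equal_angle_ring_is_180_rotation_symmetric(self):
        # with four 90-degree sectors the layout is exactly symmetric under
        # a half-turn: superior<->inferior and temporal<->nasal
        scale = ScaleSpec(fov_deg=15, frame_px=938)
        spec = RingSpec(angles_deg={"superior": 90, "inferior": 90,
                                    "nasal": 90, "temporal": 90})
        sectors = ring_sectors(spec, scale, 938, Eye.OD)
        for a, b in (("superior", "inferior"), ("temporal", "nasal")):
            np.testing.assert_array_equal(
                np.rot90(sectors.sector_mask(a), 2), sectors.sector_mask(b)
            )

    def test_ring_larger_than_frame_raises(self):
        scale = ScaleSpec(fov_deg=15, frame_px=938)
        with pytest.raises(GeometryError):
            ring_sectors(RingSpec(), scale, 200, Eye.OD)

    def test_angles_must_sum_to_360(self):
        with pytest.raises(ValueError):
            RingSpec(angles_deg={"superior": 80, "inferior": 80,
                                 "nasal": 110, "temporal": 100})


class TestLaterality:
    @pytest.mark.parametrize(
        "pos, eye, expected",
        [
            ("left", Eye.OD, "temporal"),
            ("right", Eye.OD, "nasal"),
            ("left", Eye.OS, "nasal"),
            ("right", Eye.OS, "temporal"),
            ("top", Eye.OD, "superior"),
            ("top", Eye.OS, "superior"),
            ("bottom", Eye.OD, "inferior"),
        ],
    )
    def test_mapping(self, pos, eye, expected):
        assert map_laterality(pos, eye) == expected

    def test_swapping_eye_swaps_temporal_and_nasal_only(self):
        for pos in ("left", "right"):
            od, os_ = map_laterality(pos, Eye.OD), map_laterality(pos, Eye.OS)
            assert {od, os_} == {"temporal", "nasal"}
        for pos in ("top", "bottom"):
            assert map_laterality(pos, Eye.OD) == map_laterality(pos, Eye.OS)

    def test_invalid_label_raises(self):
        with pytest.raises(ValueError):
            map_laterality("center", Eye.OD)


class TestScale:
    def test_peripapillary_default_scale(self):
        scale = ScaleSpec(fov_deg=15, frame_px=938, mm_per_deg=0.288)
        assert mm_per_px(scale) == pytest.approx(0.004606, abs=5e-7)

    def test_scale_linear_in_fov(self):
        s10 = ScaleSpec(fov_deg=10, frame_px=962)
        s20 = ScaleSpec(fov_deg=20, frame_px=962)
        assert mm_per_px(s20) == pytest.approx(2 * mm_per_px(s10), rel=1e-12)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            ScaleSpec(fov_deg=15, frame_px=938, mm_per_deg=0.0)
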