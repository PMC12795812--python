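"""Calibrated trait extraction: scale, berry traits, compactness, counts."""

import numpy as np
import pytest
from shapely import affinity
from shapely.geometry import Point, Polygon

from grapemap._geometry import convex_hull_of
from grapemap.masks import BerryMask
from grapemap.morpho import (
    CountCorrection,
    ScaleCalibration,
    aggregate_views,
    berry_traits,
    calibrate_scale,
    cluster_aspect_ratio,
    compactness_index,
    view_phenotype,
)


def disk_mask(mid, x, y, r, n=64):
    return BerryMask(mid, Point(x, y).buffer(r, quad_segs=n))


class TestScale:
    def test_known_square_reference(self):
        ref = BerryMask("ref", Polygon([(0, 0), (100, 0), (100, 100), (0, 100)]))
        cal = calibrate_scale(ref, known_size_mm=50.0)
        # second-moment extent of a square with side s is s / sqrt(3) * 2sqrt(3)... the
        # equivalent-ellipse axes of a square side 100 are 2*100/sqrt(3) ~ 115.47
        assert cal.mm_per_px == pytest.approx(50.0 / (200.0 / np.sqrt(3)), rel=1e-9)

    def test_metadata_passthrough(self):
        assert calibrate_scale(mm_per_px=0.5).mm_per_px == 0.5

    def test_occluded_reference_raises(self):
        tiny = disk_mask("ref", 0, 0, 3)
        with pytest.raises(ValueError, match="floor"):
            calibrate_scale(tiny, known_size_mm=50.0)

    def test_missing_everything_raises(self):
        with pytest.raises(ValueError):
            calibrate_scale()


class TestBerryTraits:
    def test_circle_closed_form(self):
        m = disk_mask("c", 0, 0, 20, n=512)
        area, length, width = berry_traits([m], ScaleCalibration(0.5))[0]
        assert area == pytest.approx(np.pi * 400 * 0.25, rel=1e-3)
        assert length == pytest.approx(20.0, rel=1e-3)
        assert width == pytest.approx(20.0, rel=1e-3)

    def test_axis_aligned_ellipse(self):
        e = affinity.scale(Point(0, 0).buffer(1.0, quad_segs=512), 30, 15)
        _, length, width = berry_traits([BerryMask("e", e)], ScaleCalibration(0.5))[0]
        assert length == pytest.approx(30.0, rel=1e-3)
        assert width == pytest.approx(15.0, rel=1e-3)

    def test_rotation_invariance(self):
        e = affinity.scale(Point(0, 0).buffer(1.0, quad_segs=128), 30, 15)
        t1 = berry_traits([BerryMask("e", e)], ScaleCalibration(1.0))[0]
        t2 = berry_traits([BerryMask("r", affinity.rotate(e, 53.0))], ScaleCalibration(1.0))[0]
        assert np.allclose(t1, t2, atol=1e-6)


class TestCompactness:
    def test_single_convex_berry_is_one(self):
        assert compactness_index([disk_mask("c", 0, 0, 5)]) == pytest.approx(1.0, abs=1e-9)

    def test_two_unit_squares_analytic(self, unit_squares):
        assert compactness_index(unit_squares) == pytest.approx(2 / 3, abs=1e-9)

    def test_scale_invariance(self, unit_squares):
        scaled = [affinity.scale(p, 7.3, 7.3, origin=(0, 0)) for p in unit_squares]
        assert compactness_index(scaled) == pytest.approx(compactness_index(unit_squares), abs=1e-9)

    def test_monte_carlo_hull_oracle(self):
        """Hull area via rejection sampling agrees within 0.5%."""
        from shapely import contains_xy

        rng = np.random.default_rng(2)
        for rep in range(5):
            disks = []
            while len(disks) < 10:
                c, r = rng.uniform(0, 100, 2), rng.uniform(3, 8)
                if all(np.hypot(*(c - o[0])) > r + o[1] for o in disks):
                    disks.append((c, r))
            polys = [Point(*c).buffer(r, quad_segs=64) for c, r in disks]
            hull = convex_hull_of(polys)
            x0, y0, x1, y1 = hull.bounds
            pts = rng.uniform([x0, y0], [x1, y1], (120_000, 2))
            frac = contains_xy(hull, pts[:, 0], pts[:, 1]).mean()
            mc = sum(p.area for p in polys) / (frac * (x1 - x0) * (y1 - y0))
            assert compactness_index(polys) == pytest.approx(mc, rel=0.005)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compactness_index([])

    def test_matches_simulator_truth_without_occlusion(self):
        from grapemap.simulate import ClusterSimConfig, simulate_cluster

        cfg = ClusterSimConfig(n_berries=15, allow_overlap=False, n_artifacts=0, seed=2)
        masks_per_angle, truth = simulate_cluster(cfg)
        est = compactness_index(masks_per_angle[0])
        assert est == pytest.approx(truth.true_compactness, rel=1e-6)


class TestAspectRatio:
    def test_rect_lattice_ratio_near_four(self):
        polys = [Point(x, y).buffer(0.5) for x in np.linspace(0, 40, 9) for y in np.linspace(0, 10, 3)]
        assert cluster_aspect_ratio(polys) == pytest.approx(4.0, rel=0.1)

    def test_radial_symmetry_near_one(self):
        polys = [
            Point(10 * np.cos(a), 10 * np.sin(a)).buffer(1.0)
            for a in np.linspace(0, 2 * np.pi, 12, endpoint=False)
        ]
        assert cluster_aspect_ratio(polys) == pytest.approx(1.0, abs=0.05)

    def test_two_circles_closed_form(self):
        """Centres 10 apart, radius 1: extent along the axis 12, across 2."""
        polys = [Point(0, 0).buffer(1, quad_segs=256), Point(10, 0).buffer(1, quad_segs=256)]
        assert cluster_aspect_ratio(polys) == pytest.approx(6.0, rel=1e-3)

    def test_needs_two_masks(self):
        with pytest.raises(ValueError):
            cluster_aspect_ratio([Point(0, 0).buffer(1)])


class TestCountCorrection:
    def test_exact_line_recovered(self):
        x = np.array([10, 20, 30, 40.0])
        model = CountCorrection().fit(x, 1.2 * x + 3)
        assert model.slope_ == pytest.approx(1.2, abs=1e-9)
        assert model.intercept_ == pytest.approx(3.0, abs=1e-9)
        assert model.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_identity_data(self):
        x = np.array([5, 9, 13.0])
        model = CountCorrection().fit(x, x)
        assert model.slope_ == pytest.approx(1.0, abs=1e-9)
        assert model.intercept_ == pytest.approx(0.0, abs=1e-9)

    def test_max_angle_rule_arithmetic(self):
        model = CountCorrection.from_dict({"slope": 1.2, "intercept": 3.0})
        assert model.correct((40, 45)) == pytest.approx(57.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            CountCorrection().fit([5, 5, 5], [6, 7, 8])

    def test_json_roundtrip(self):
        m = CountCorrection().fit([1, 2, 3.0], [2, 4, 6.0])
        m2 = CountCorrection.from_dict(m.to_dict())
        assert m2.slope_ == m.slope_ and m2.intercept_ == m.intercept_


class TestAggregateViews:
    def test_identical_views_unchanged(self):
        masks = [disk_mask(f"m{i}", 30 * i, 0, 5) for i in range(4)]
        v = view_phenotype("c1", masks, ScaleCalibration(1.0))
        agg = aggregate_views([v, v])
        assert agg.compactness == pytest.approx(v.compactness)
        assert agg.mean_berry_area == pytest.approx(v.mean_berry_area)
        assert agg.berry_count_corrected == 4.0

    def test_compactness_mean_of_views(self):
        masks = [disk_mask(f"m{i}", 30 * i, 0, 5) for i in range(3)]
        v1 = view_phenotype("c1", masks, ScaleCalibration(1.0))
        v2 = view_phenotype("c1", masks, ScaleCalibration(1.0))
        v1.compactness, v2.compactness = 0.18, 0.20
        assert aggregate_views([v1, v2]).compactness == pytest.approx(0.19)

    def test_single_view_flagged(self):
        masks = [disk_mask(f"m{i}", 30 * i, 0, 5) for i in range(3)]
        agg = aggregate_views([view_phenotype("c1", masks, ScaleCalibration(1.0))])
        assert "one-view" in agg.flags

    def test_three_views_rejected(self):
        masks = [disk_mask(f"m{i}", 30 * i, 0, 5) for i in range(3)]
        v = view_phenotype("c1", masks, ScaleCalibration(1.0))
        with pytest.raises(ValueError):
            aggregate_views([v, v, v])

    def test_correction_applied_to_max_angle(self):
        masks40 = [disk_mask(f"m{i}", 30 * i, 0, 5) for i in range(40)]
        masks45 = [disk_mask(f"m{i}", 30 * i, 0, 5) for i in range(45)]
        v1 = view_phenotype("c1", masks40, ScaleCalibration(1.0))
        v2 = view_phenotype("c1", masks45, ScaleCalibration(1.0))
        model = CountCorrection.from_dict({"slope": 1.2, "intercept": 3.0})
        assert aggregate_views([v1, v2], model).berry_count_corrected == pytest.approx(57.0)
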