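"""Window filtering, chain linking, Bezier fitting and entrance angles."""

import math

import numpy as np
import pytest

from pesrnfl.bundles import (Bundle, FitError, assemble_bundles, bezier_eval,
                             entrance_angle, filter_extractions, fit_bezier,
                             link_extractions)
from pesrnfl.config import BundleConfig
from pesrnfl.extraction import PointwiseExtraction
from pesrnfl.geometry import AngleWindow
from pesrnfl.landmarks import OnhGeometry
from pesrnfl.refmaps import RegionPartition, RegionWindows


def _ex(x, y, theta, region_id=1):
    return PointwiseExtraction(centroid_px=(0.0, 0.0), theta=float(theta),
                               n_pixels=25, region_id=region_id,
                               centroid_deg=(float(x), float(y)))


def _windows(mapping):
    return RegionWindows(partition=RegionPartition(),
                         windows={rid: w for rid, w in mapping.items()},
                         margin=0.0)


class TestFilterExtractions:
    def test_window_boundary_is_closed(self):
        w = _windows({1: AngleWindow(10.0, 30.0)})
        kept = filter_extractions([_ex(0, 0, 40.0), _ex(0, 0, 10.0)], w)
        assert len(kept) == 2

    def test_one_degree_outside_removed(self):
        w = _windows({1: AngleWindow(10.0, 30.0)})
        assert filter_extractions([_ex(0, 0, 41.0)], w) == []
        assert filter_extractions([_ex(0, 0, 9.0)], w) == []

    def test_full_circle_windows_are_identity(self):
        w = _windows({i: AngleWindow(0.0, 360.0) for i in range(1, 11)})
        exs = [_ex(i, 0, 37.0 * i, region_id=1 + i % 10) for i in range(20)]
        assert filter_extractions(exs, w) == exs


class TestLinkExtractions:
    ONH = (15.0, 2.0)

    def test_collinear_identical_theta_forms_one_chain(self):
        exs = [_ex(14.0 - i, 2.0, 0.0) for i in range(11)]
        chains = link_extractions(exs, 1.5, 25.0, 35.0, self.ONH)
        assert len(chains) == 1 and len(chains[0]) == 11

    def test_orientation_outlier_excluded(self):
        # spacing 0.7 with radius 1.5: the chain can bridge past the
        # mis-oriented member, which ends up a singleton
        exs = [_ex(14.0 - 0.7 * i, 2.0, 0.0 if i != 5 else 40.0)
               for i in range(11)]
        chains = link_extractions(exs, 1.5, 25.0, 35.0, self.ONH)
        assert sorted(len(c) for c in chains) == [1, 10]

    def test_parallel_rows_beyond_radius_stay_separate(self):
        exs = [_ex(14.0 - i, 2.0, 0.0) for i in range(11)] \
            + [_ex(14.0 - i, 6.0, 0.0) for i in range(11)]
        chains = link_extractions(exs, 1.5, 25.0, 35.0, self.ONH)
        assert sorted(len(c) for c in chains) == [11, 11]
        ys = {round(c[0].centroid_deg[1], 1) for c in chains}
        assert ys == {2.0, 6.0}

    def test_each_extraction_used_once(self):
        rng = np.random.default_rng(0)
        exs = [_ex(x, y, t) for x, y, t in
               zip(rng.uniform(-10, 10, 60), rng.uniform(-10, 10, 60),
                   rng.uniform(0, 360, 60))]
        chains = link_extractions(exs, 3.0, 25.0, 35.0, self.ONH)
        flat = [id(e) for c in chains for e in c]
        assert len(flat) == len(set(flat)) == 60


class TestFitBezier:
    def test_square_system_interpolates(self):
        rng = np.random.default_rng(1)
        markers = np.cumsum(rng.uniform(0.2, 1.0, (11, 2)), axis=0)
        cp = fit_bezier(markers, order_n=10)
        curve = bezier_eval(cp, np.linspace(0, 1, 11))
        # endpoints coincide; interior matches at the chord parameters
        from pesrnfl.bundles import chord_length_params

        t = chord_length_params(markers)
        fitted = bezier_eval(cp, t)
        assert np.abs(fitted - markers).max() < 1e-6
        assert np.abs(curve[0] - markers[0]).max() < 1e-9
        assert np.abs(curve[-1] - markers[-1]).max() < 1e-9

    def test_collinear_markers_give_collinear_control_points(self):
        t = np.linspace(0, 1, 15)
        markers = np.column_stack([1.0 + 3.0 * t, 2.0 - 1.5 * t])
        cp = fit_bezier(markers, order_n=10)
        # all control points on the line y = 2 - 0.5 (x - 1)
        resid = (cp[:, 1] - 2.0) + 0.5 * (cp[:, 0] - 1.0)
        assert np.abs(resid).max() < 1e-6

    def test_recovers_known_degree10_curve(self):
        rng = np.random.default_rng(5)
        true_cp = rng.uniform(-5, 5, (11, 2))
        t = np.sort(rng.uniform(0, 1, 30))
        t[0], t[-1] = 0.0, 1.0
        markers = bezier_eval(true_cp, t)
        cp = fit_bezier(markers, order_n=10, params=t)
        assert np.abs(cp - true_cp).max() < 1e-6

    def test_too_few_markers_rejected(self):
        with pytest.raises(FitError):
            fit_bezier(np.zeros((10, 2)), order_n=10)

    def test_nested_orders_do_not_increase_residual(self):
        rng = np.random.default_rng(9)
        t = np.linspace(0, 1, 40)
        markers = np.column_stack([t * 10, np.sin(3 * t) + 0.05
                                   * rng.standard_normal(40)])
        prev = None
        for n in range(4, 11):
            cp = fit_bezier(markers, order_n=n, params=t)
            resid = float(((bezier_eval(cp, t) - markers) ** 2).sum())
            if prev is not None:
                assert resid <= prev + 1e-9
            prev = resid


class TestEntranceAngle:
    CIRCLE = OnhGeometry(center_deg=(15.0, 2.0), radius_major=2.0,
                         radius_minor=2.0, orientation=0.0)

    def _line_cp(self, p0, p1, n=10):
        t = np.linspace(0, 1, n + 1)[:, None]
        return (1 - t) * np.asarray(p0, float) + t * np.asarray(p1, float)

    def test_horizontal_temporal_approach_enters_at_180(self):
        cp = self._line_cp((5.0, 2.0), (15.0, 2.0))
        assert entrance_angle(cp, self.CIRCLE) == pytest.approx(180.0, abs=0.01)

    def test_line_circle_matches_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ang = rng.uniform(0, 2 * math.pi)
            p0 = (15.0 + 8.0 * math.cos(ang), 2.0 + 8.0 * math.sin(ang))
            jitter = rng.uniform(-0.15, 0.15)
            direction = np.array([15.0, 2.0]) - p0 \
                + 8.0 * jitter * np.array([-math.sin(ang), math.cos(ang)])
            p1 = p0 + 1.1 * direction
            got = entrance_angle(self._line_cp(p0, p1), self.CIRCLE)
            # closed form: first intersection of the ray with the circle
            d = direction / np.linalg.norm(direction)
            f = np.array(p0) - (15.0, 2.0)
            b = 2 * float(f @ d)
            c = float(f @ f) - 4.0
            disc = b * b - 4 * c
            t_hit = (-b - math.sqrt(disc)) / 2.0
            hit = p0 + t_hit * d
            expected = math.degrees(math.atan2(-(hit[1] - 2.0), hit[0] - 15.0)) % 360
            assert got == pytest.approx(expected, abs=0.01)

    def test_curve_outside_returns_absent(self):
        cp = self._line_cp((5.0, 10.0), (25.0, 10.0))
        assert entrance_angle(cp, self.CIRCLE) is None


class TestAssembleBundles:
    def test_minimum_marker_rule_enforced(self):
        onh = TestEntranceAngle.CIRCLE
        exs = [_ex(14.0 - 0.8 * i, 2.0, 0.0) for i in range(8)]  # too short
        assert assemble_bundles(exs, onh) == []

    def test_straight_chain_yields_entering_bundle(self):
        onh = TestEntranceAngle.CIRCLE
        exs = [_ex(14.0 - 0.8 * i, 2.0, 0.0) for i in range(15)]
        bundles = assemble_bundles(exs, onh)
        assert len(bundles) == 1
        b = bundles[0]
        assert len(b.markers) == 15
        assert b.entrance_angle == pytest.approx(180.0, abs=0.5)
        # markers ordered outward-in
        d = np.hypot(b.markers[:, 0] - 15.0, b.markers[:, 1] - 2.0)
        assert np.all(np.diff(d) < 0)

    def test_bundle_count_non_increasing_in_tolerances(self):
        rng = np.random.default_rng(2)
        exs = []
        for row in range(4):
            theta0 = rng.uniform(0, 360)
            exs += [_ex(14.0 - 0.8 * i, 2.0 + 3.0 * row,
                        (theta0 + rng.uniform(-20, 20)) % 360)
                    for i in range(15)]
        onh = TestEntranceAngle.CIRCLE
        counts = []
        for tol in (40.0, 25.0, 10.0, 4.0):
            cfg = BundleConfig(tol_individual_deg=tol, tol_group_deg=tol + 10)
            counts.append(len(assemble_bundles(exs, onh, cfg)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
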