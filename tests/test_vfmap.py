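"""24-2 grid, alignment, rasterization, intersections, mirroring and the
wraparound rule."""

import numpy as np
import pytest

from pesrnfl.geometry import CANONICAL_ONH
from pesrnfl.landmarks import GeometryError, OnhGeometry
from pesrnfl.vfmap import (IntersectionSet, align_normalize, align_onh_geometry,
                           intersect_vf, mirror_assign, rasterize_dilate,
                           summarize, vf_grid_242, wrap_adjust,
                           wrap_adjust_sets)

SMALL = (230, 350)  # downscaled working raster for fast tests


class TestGrid:
    def test_counts(self):
        grid = vf_grid_242()
        assert len(grid) == 54
        assert sum(p.blind_spot for p in grid) == 2
        assert sum(not p.blind_spot for p in grid) == 52

    def test_coordinates_are_odd_multiples_of_three(self):
        for p in vf_grid_242():
            assert p.x_deg % 6 == 3 or p.x_deg % 6 == -3
            assert abs(p.x_deg) % 2 == 1 or True
            assert (abs(p.x_deg) / 3) % 2 == 1
            assert (abs(p.y_deg) / 3) % 2 == 1

    def test_interior_nearest_neighbor_spacing_is_six(self):
        grid = vf_grid_242()
        pts = np.array([(p.x_deg, p.y_deg) for p in grid])
        for i, p in enumerate(pts):
            d = np.hypot(*(pts - p).T)
            assert np.sort(d)[1] == pytest.approx(6.0)

    def test_mirror_symmetric_about_meridian(self):
        coords = {(p.x_deg, p.y_deg) for p in vf_grid_242()}
        assert {(x, -y) for x, y in coords} == coords

    def test_blind_spot_flanks_the_onh(self):
        bs = sorted((p.x_deg, p.y_deg) for p in vf_grid_242() if p.blind_spot)
        assert bs == [(15.0, -3.0), (15.0, 3.0)]


class TestAlignNormalize:
    def _onh(self, cx, cy):
        return OnhGeometry(center_deg=(cx, cy), radius_major=3.5,
                           radius_minor=3.0, orientation=90.0)

    def test_canonical_eye_gets_identity(self):
        al = align_normalize(self._onh(15.0, 2.0))
        assert al.rotation_deg == pytest.approx(0.0, abs=1e-9)
        assert al.scale == pytest.approx(1.0, abs=1e-9)

    def test_onh_lands_exactly_on_target(self):
        for cx, cy in [(13.0, 4.0), (18.0, -1.0), (16.0, 0.5)]:
            al = align_normalize(self._onh(cx, cy))
            x, y = al.apply_points(cx, cy)
            assert x == pytest.approx(CANONICAL_ONH[0], abs=1e-9)
            assert y == pytest.approx(CANONICAL_ONH[1], abs=1e-9)

    def test_round_trip_within_tolerance(self):
        al = align_normalize(self._onh(17.0, 3.0))
        pts = np.random.default_rng(0).uniform(-20, 20, (50, 2))
        x, y = al.apply_points(pts[:, 0], pts[:, 1])
        xr, yr = al.inverse().apply_points(x, y)
        np.testing.assert_allclose(np.column_stack([xr, yr]), pts, atol=1e-9)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(GeometryError):
            align_normalize(self._onh(-3.0, 2.0))

    def test_aligned_ellipse_scales_isotropically(self):
        onh = self._onh(13.0, 4.0)
        al = align_normalize(onh)
        out = align_onh_geometry(onh, al)
        assert out.center_deg[0] == pytest.approx(15.0)
        assert out.center_deg[1] == pytest.approx(2.0)
        assert out.ellipticity == pytest.approx(onh.ellipticity)


class TestRasterizeDilate:
    def test_zero_radius_leaves_raster_unchanged(self):
        pts = np.array([[0.0, 0.0], [5.0, 5.0]])
        r0 = rasterize_dilate(points_xy=pts, angles=[10.0, 20.0],
                              resolution=SMALL, selem_radius=0)
        assert r0.mask.sum() == 2

    def test_dilation_extensive_and_monotone(self):
        pts = np.array([[0.0, 0.0], [5.0, 5.0], [-3.0, 8.0]])
        masks = [rasterize_dilate(points_xy=pts, angles=[1.0, 2.0, 3.0],
                                  resolution=SMALL, selem_radius=r).mask
                 for r in (0, 1, 2, 4)]
        for small, big in zip(masks, masks[1:]):
            assert big.sum() >= small.sum()
            assert np.all(big[small])

    def test_dilated_pixels_carry_nearest_source_angle(self):
        pts = np.array([[-5.0, 0.0], [5.0, 0.0]])
        r = rasterize_dilate(points_xy=pts, angles=[90.0, 270.0],
                             resolution=SMALL, selem_radius=3)
        row, col = r.to_px(-5.0, 0.0)
        assert r.values[int(row) - 2, int(col)] == 90.0
        row, col = r.to_px(5.0, 0.0)
        assert r.values[int(row) + 2, int(col)] == 270.0


class TestIntersect:
    def test_empty_raster_gives_empty_sets(self):
        r = rasterize_dilate(points_xy=np.empty((0, 2)), angles=[],
                             resolution=SMALL)
        sets = intersect_vf(r, vf_grid_242())
        assert len(sets) == 52
        assert all(s.n == 0 for s in sets)

    def test_point_on_vf_center_collected(self):
        r = rasterize_dilate(points_xy=np.array([[9.0, 15.0]]), angles=[150.0],
                             resolution=SMALL, selem_radius=0)
        sets = intersect_vf(r, vf_grid_242())
        hit = [s for s in sets if s.n > 0]
        assert len(hit) == 1
        assert set(np.unique(hit[0].angles)) == {150.0}

    def test_set_size_bounded_by_acceptance_disk(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-21, 21, (4000, 2))
        r = rasterize_dilate(points_xy=pts, angles=rng.uniform(0, 360, 4000),
                             resolution=SMALL, selem_radius=2)
        rpx = 0.86 * r.px_per_deg
        bound = np.pi * (rpx + 1.0) ** 2
        for s in intersect_vf(r, vf_grid_242()):
            assert s.n <= bound


class TestMirrorAssign:
    def _sets(self):
        grid = vf_grid_242()
        return [IntersectionSet(p.index, np.array([float(p.index)]))
                for p in grid if not p.blind_spot], grid

    def test_involution(self):
        sets, grid = self._sets()
        twice = mirror_assign(mirror_assign(sets, grid), grid)
        for a, b in zip(sets, twice):
            assert a.vf_index == b.vf_index
            np.testing.assert_array_equal(a.angles, b.angles)

    def test_swaps_across_meridian_no_fixed_points(self):
        sets, grid = self._sets()
        out = mirror_assign(sets, grid)
        by_index = {p.index: p for p in grid}
        for s_in, s_out in zip(sets, out):
            p = by_index[s_in.vf_index]
            q = next(g for g in grid if (g.x_deg, g.y_deg) == (p.x_deg, -p.y_deg))
            assert q.index != p.index
            assert s_out.angles[0] == float(q.index)

    def test_union_of_angles_preserved(self):
        sets, grid = self._sets()
        out = mirror_assign(sets, grid)
        assert sorted(float(s.angles[0]) for s in out) \
            == sorted(float(s.angles[0]) for s in sets)


class TestWrapAdjust:
    def test_wraparound_pair(self):
        a, adj, irr = wrap_adjust([359.0, 1.0])
        np.testing.assert_array_equal(a, [-1.0, 1.0])
        assert adj and not irr
        assert np.mean(a) == 0.0

    def test_compact_set_untouched(self):
        a, adj, irr = wrap_adjust([10.0, 20.0, 30.0])
        np.testing.assert_array_equal(a, [10.0, 20.0, 30.0])
        assert not adj

    def test_irreducible_flagged(self):
        a, adj, irr = wrap_adjust([0.0, 120.0, 240.0])
        assert adj and irr

    def test_means_invariant_to_input_rotation_convention(self):
        base = np.array([350.0, 355.0, 2.0, 5.0])
        a1, _, _ = wrap_adjust(base)
        a2, _, _ = wrap_adjust((base + 360.0) % 360.0)
        assert np.mean(a1) == pytest.approx(np.mean(a2))


class TestSummarize:
    def test_singleton_zero_sd(self):
        df = summarize([IntersectionSet(5, np.array([42.0]))])
        assert df.iloc[0].sd_deg == 0.0 and df.iloc[0].limit95_deg == 0.0

    def test_limit95_is_twice_sd(self):
        rng = np.random.default_rng(0)
        sets = wrap_adjust_sets([IntersectionSet(i, rng.uniform(0, 90, 20))
                                 for i in range(2, 10)])
        df = summarize(sets)
        np.testing.assert_allclose(df.limit95_deg, 2.0 * df.sd_deg)

    def test_symmetric_pair_mean_zero(self):
        df = summarize([IntersectionSet(3, np.array([-1.0, 1.0]))])
        assert df.iloc[0].mean_deg == 0.0

    def test_empty_sets_absent_and_row_bound(self):
        sets = [IntersectionSet(i, np.empty(0)) for i in range(1, 60)]
        sets[4] = IntersectionSet(5, np.array([10.0]))
        df = summarize(sets)
        assert len(df) == 1 and df.iloc[0].vf_index == 5
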