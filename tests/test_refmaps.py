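"""Trajectory model, reference map, region windows and ONH sectors."""

import math

import numpy as np
import pytest

from pesrnfl.geometry import CANONICAL_ONH, circ_abs_diff, theta_from_vec
from pesrnfl.preprocess import ParameterError
from pesrnfl.refmaps import (ConfigError, OnhSectors, RegionPartition,
                             WindowingError, build_reference_map,
                             garway_heath_sectors, reference_coverage,
                             region_windows, trajectory)


class TestTrajectory:
    def test_starts_at_phi0_on_r0_circle(self):
        for phi0 in (-170.0, -90.0, -30.0, 0.0, 45.0, 121.0, 179.0):
            tr = trajectory(phi0, r_max=20.0)
            assert tr.samples[0, 0] == pytest.approx(4.0)
            assert tr.samples[0, 1] == pytest.approx(phi0)

    def test_nasal_trajectories_are_straight_radial(self):
        tr = trajectory(30.0, r_max=20.0)
        assert tr.b == 0.0
        np.testing.assert_allclose(tr.samples[:, 1], 30.0)
        # all samples lie on the ray from the ONH center
        d = tr.xy - np.array(CANONICAL_ONH)
        ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
        np.testing.assert_allclose(ang, 30.0, atol=1e-9)

    def test_phi_strictly_monotone_for_curved_paths(self):
        sup = trajectory(121.0, r_max=25.0)
        assert np.all(np.diff(sup.samples[:, 1]) > 0)  # b > 0 superior
        inf = trajectory(-121.0, r_max=25.0)
        assert np.all(np.diff(inf.samples[:, 1]) < 0)  # b < 0 inferior

    def test_r_strictly_increasing(self):
        tr = trajectory(100.0, r_max=30.0, dr=0.5)
        assert np.all(np.diff(tr.samples[:, 0]) > 0)

    def test_domain_and_dr_validation(self):
        with pytest.raises(ParameterError):
            trajectory(200.0)
        with pytest.raises(ParameterError):
            trajectory(-181.0)
        with pytest.raises(ParameterError):
            trajectory(90.0, dr=0.0)

    def test_hemifield_noncrossing_on_1deg_grid(self):
        # same-hemifield trajectories keep their angular order at every
        # shared radius
        for phi0s in (np.arange(61.0, 180.0, 1.0), -np.arange(61.0, 180.0, 1.0)[::-1]):
            rs = np.arange(4.0, 25.0, 1.0)
            prev = None
            for phi0 in phi0s:
                tr = trajectory(float(phi0), r_max=25.0, dr=1.0)
                phi = np.interp(rs, tr.samples[:, 0], tr.samples[:, 1],
                                right=np.nan)
                if prev is not None:
                    both = np.isfinite(phi) & np.isfinite(prev)
                    assert np.all(phi[both] > prev[both])
                prev = phi

    def test_hemifields_respect_the_raphe(self):
        # superior paths stay at phi >= 0, inferior at phi <= 0 (clipping
        # stops them at the raphe crossing)
        for phi0 in np.arange(61.0, 180.0, 7.0):
            assert np.all(trajectory(float(phi0), r_max=40.0).samples[:, 1] >= 0)
        for phi0 in -np.arange(61.0, 180.0, 7.0):
            assert np.all(trajectory(float(phi0), r_max=40.0).samples[:, 1] <= 0)

    def test_entrance_angle_convention(self):
        # phi0 = 121 (superotemporal) maps to 239 deg nasal-origin clockwise
        assert trajectory(121.0).entrance_angle == pytest.approx(239.0)


class TestReferenceMap:
    def test_deterministic_builds(self):
        a = build_reference_map(dphi0=4.0, px_per_deg=2.0)
        b = build_reference_map(dphi0=4.0, px_per_deg=2.0)
        assert a.angle.tobytes() == b.angle.tobytes()
        assert a.valid.tobytes() == b.valid.tobytes()

    def test_coverage_of_retina_pixels(self, ctx):
        assert reference_coverage(ctx.refmap) >= 0.95

    @staticmethod
    def _analytic_tangent(phi0, r):
        """Closed-form directed tangent (toward the ONH) of the trajectory
        started at phi0, at radius r: differentiate the power law and
        combine the radial and tangential velocity components."""
        from pesrnfl.refmaps import R0, _coefficients

        b, c = _coefficients(phi0)
        dphi_dr = math.radians(b * c * (r - R0) ** (c - 1.0)) if r > R0 else 0.0
        pr = math.radians(phi0 + b * (r - R0) ** c)
        d = np.array([math.cos(pr), math.sin(pr)]) \
            + r * dphi_dr * np.array([-math.sin(pr), math.cos(pr)])
        return theta_from_vec(-d[0], -d[1])

    def test_traced_tangents_match_analytic_derivative(self):
        # the numerical tangents stored along a trace equal the closed-form
        # derivative of the power-law model (interior samples)
        for phi0 in (-150.0, -100.0, -70.0, 80.0, 121.0, 160.0):
            tr = trajectory(float(phi0), r_max=20.0, dr=0.05)
            th = tr.tangent_theta()
            for i in range(5, len(tr.xy) - 5, 20):
                r = tr.samples[i, 0]
                assert float(circ_abs_diff(th[i],
                                           self._analytic_tangent(phi0, r))) < 1.0

    def test_papillomacular_axis_tangent_points_at_onh(self, ctx):
        # nearing the disc, papillomacular fibers run nearly straight along
        # the fovea-ONH direction (their curvature concentrates at the
        # foveal end of the axis)
        target = theta_from_vec(*CANONICAL_ONH)
        xs = np.linspace(6.0, 10.0, 9)
        ys = xs * CANONICAL_ONH[1] / CANONICAL_ONH[0]
        angs = ctx.refmap.sample(xs, ys)
        valid = np.isfinite(angs)
        assert valid.mean() > 0.8
        assert np.all(circ_abs_diff(angs[valid], target) <= 15.0)


class TestRegionWindows:
    def test_partition_covers_and_is_exclusive(self):
        part = RegionPartition()
        rng = np.random.default_rng(0)
        x = rng.uniform(-22, 22, 4000)
        y = rng.uniform(-22, 22, 4000)
        ids = part.assign(x, y)
        assert ids.min() >= 1 and ids.max() <= 10
        assert len(np.unique(ids)) == 10

    def test_margin_zero_contains_every_valid_angle(self, ctx):
        w = region_windows(ctx.refmap, margin=0.0)
        n = ctx.refmap.angle.shape[0]
        rows, cols = np.mgrid[0:n, 0:n]
        x, y = ctx.refmap.to_deg(rows, cols)
        region = w.partition.assign(x, y)
        for rid in range(1, 11):
            sel = (region == rid) & ctx.refmap.valid
            assert bool(np.all(w.windows[rid].contains(ctx.refmap.angle[sel])))

    def test_margin_widens_by_twice_margin(self, ctx):
        w0 = region_windows(ctx.refmap, margin=0.0)
        w10 = region_windows(ctx.refmap, margin=10.0)
        for rid in range(1, 11):
            expected = min(w0.windows[rid].width + 20.0, 360.0)
            assert w10.windows[rid].width == pytest.approx(expected)

    def test_empty_region_raises(self):
        ref = build_reference_map(dphi0=4.0, px_per_deg=2.0)
        ref.valid[:] = False
        with pytest.raises(WindowingError):
            region_windows(ref)

    def test_raphe_full_circle_flag(self, ctx):
        w = region_windows(ctx.refmap, margin=0.0, raphe_full_circle=True)
        assert w.windows[10].width == 360.0


class TestOnhSectors:
    def test_default_widths_sum_to_360(self):
        s = garway_heath_sectors()
        assert sum(w for _, _, w in s.sectors) == pytest.approx(360.0)

    def test_each_angle_in_exactly_one_sector(self):
        s = garway_heath_sectors()
        for a in np.arange(0.0, 360.0, 0.5):
            hits = [(a - lo) % 360.0 < w for _, lo, w in s.sectors]
            assert sum(hits) == 1

    def test_half_open_boundary_convention(self):
        s = garway_heath_sectors()
        assert s.sector_of(131.0) == "temporal"
        assert s.sector_of(221.0) == "superotemporal"
        assert s.sector_of(220.999) == "temporal"

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            OnhSectors((("a", 0.0, 120.0), ("b", 120.0, 120.0)))
        with pytest.raises(ConfigError):
            OnhSectors((("a", 0.0, 180.0), ("b", 90.0, 180.0)))

    def test_round_trips_through_json(self, tmp_path):
        s = garway_heath_sectors()
        path = tmp_path / "sectors.json"
        s.to_json(path)
        assert OnhSectors.from_json(path) == s
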