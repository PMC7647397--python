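import math

import numpy as np
import pytest

import widefield_mc as wm
from widefield_mc.collection import CollectionResult, is_collected, surface_spread_quantiles


def _make_result(xy, weights=None, depth=0.5):
    xy = np.asarray(xy, dtype=float)
    w = np.ones(len(xy)) if weights is None else np.asarray(weights, float)
    return CollectionResult(
        source_depth=depth, source_xy=(0.0, 0.0), n_emitted=len(xy),
        emitted_weight=float(len(xy)), collected_weight=float(w.sum()),
        exit_positions=xy, collected_weights=w, seed=0,
    )


class TestIsCollected:
    def test_normal_exit_at_center(self, objective):
        assert is_collected(np.array([0, 0, -1.0]), np.array([0, 0]), objective)
        assert is_collected(np.array([0, 0, -1.0]), np.array([0, 0]), objective,
                            criterion="cone")

    def test_cone_rejects_beyond_na_angle(self, objective):
        th = math.radians(6.0)
        d = np.array([math.sin(th), 0.0, -math.cos(th)])
        assert not is_collected(d, np.array([0, 0]), objective, criterion="cone")
        th = math.radians(5.0)
        d = np.array([math.sin(th), 0.0, -math.cos(th)])
        assert is_collected(d, np.array([0, 0]), objective, criterion="cone")

    def test_aperture_accepts_up_to_front_window(self, objective):
        # on-axis, the 7 mm window at 56.3 mm subtends atan(7/56.3) = 7.09 deg
        for deg, expected in ((6.5, True), (7.5, False)):
            th = math.radians(deg)
            d = np.array([math.sin(th), 0.0, -math.cos(th)])
            assert is_collected(d, np.array([0, 0]), objective) is expected

    def test_vignetting_outside_fov(self, objective):
        pos = np.array([objective.field_of_view_diameter / 2 + 0.1, 0.0])
        assert not is_collected(np.array([0, 0, -1.0]), pos, objective)

    def test_inward_direction_rejected(self, objective):
        with pytest.raises(ValueError):
            is_collected(np.array([0, 0, 1.0]), np.array([0, 0]), objective)


class TestVacuumLimits:
    def test_cone_collection_equals_solid_angle_fraction(self, vacuum_scene, objective):
        """No scattering or absorption: the collected fraction from a
        surface source is the acceptance-cone solid angle over 4 pi,
        (1 - cos 5.74 deg)/2 = 0.2505%."""
        res = wm.run_collection_from_point(
            vacuum_scene, 0.0, objective, 200_000, seed=42, criterion="cone"
        )
        expected = (1.0 - objective.cos_theta_max) / 2.0
        se = math.sqrt(expected * (1 - expected) / 200_000)
        assert res.collected_fraction == pytest.approx(expected, abs=3 * se)

    def test_aperture_collection_matches_window_solid_angle(self, vacuum_scene, objective):
        res = wm.run_collection_from_point(
            vacuum_scene, 0.0, objective, 200_000, seed=43
        )
        cos_w = math.cos(math.atan(7.0 / 56.3))
        expected = (1.0 - cos_w) / 2.0
        se = math.sqrt(expected * (1 - expected) / 200_000)
        assert res.collected_fraction == pytest.approx(expected, abs=3 * se)

    def test_vacuum_surface_source_has_no_spread(self, vacuum_scene, objective):
        res = wm.run_collection_from_point(vacuum_scene, 0.0, objective, 100_000, seed=44)
        q = surface_spread_quantiles(res, (0.5, 0.95))
        assert q[0.5] < 0.01 and q[0.95] < 0.01


class TestSpreadQuantiles:
    def test_matches_sort_oracle_with_weights(self):
        rng = np.random.default_rng(7)
        n = 4000
        xy = rng.normal(size=(n, 2)) * 0.3
        w = rng.random(n)
        res = _make_result(xy, w)
        q = surface_spread_quantiles(res, (0.5, 0.9), convention="radial")
        # oracle: explicit scan of the weighted empirical CDF of radii
        r = np.hypot(xy[:, 0], xy[:, 1])
        order = np.argsort(r)
        r_s, w_s = r[order], w[order]
        cum = (np.cumsum(w_s) - 0.5 * w_s) / w_s.sum()
        for f in (0.5, 0.9):
            i = np.searchsorted(cum, f)
            lo, hi = r_s[i - 1], r_s[i]
            assert lo <= q[f] / 2 <= hi

    def test_marginal_narrower_than_radial(self):
        rng = np.random.default_rng(8)
        res = _make_result(rng.normal(size=(5000, 2)))
        qm = surface_spread_quantiles(res, (0.5,), convention="marginal")
        qr = surface_spread_quantiles(res, (0.5,), convention="radial")
        # Rayleigh median 1.177 sigma vs half-normal median 0.674 sigma
        assert qm[0.5] < qr[0.5]
        assert qr[0.5] / qm[0.5] == pytest.approx(1.177 / 0.674, rel=0.1)

    def test_bin_width_rounds_up_to_whole_bins(self):
        res = _make_result([[0.0005 * (i % 3), 0.0] for i in range(300)])
        q = surface_spread_quantiles(res, (0.5,), bin_width=0.01)
        assert q[0.5] == pytest.approx(0.01)

    def test_too_few_collected(self):
        res = _make_result([[0.0, 0.0]] * 10)
        with pytest.raises(ValueError):
            surface_spread_quantiles(res)


class TestDepthDependence:
    def test_diameters_grow_with_source_depth(
        self, small_collection_surface, small_collection_1mm, window_scene, objective
    ):
        mid = wm.run_collection_from_point(window_scene, 0.5, objective, 100_000, seed=55)
        qs = [
            surface_spread_quantiles(r, (0.5, 0.95))
            for r in (small_collection_surface, mid, small_collection_1mm)
        ]
        assert qs[0][0.5] <= qs[1][0.5] <= qs[2][0.5]
        assert qs[0][0.95] <= qs[1][0.95] <= qs[2][0.95]

    def test_deep_sources_still_collected(
        self, small_collection_surface, small_collection_1mm
    ):
        """Photons from 1 mm deep contribute nearly as much per photon
        as surface photons (within a factor of ~2)."""
        f0 = small_collection_surface.collected_fraction
        f1 = small_collection_1mm.collected_fraction
        assert 0.4 < f1 / f0 < 1.5

    def test_vignetting_smaller_fov_reduces_collection_and_spread(
        self, window_scene, objective
    ):
        import dataclasses

        narrow = dataclasses.replace(objective, field_of_view_diameter=4.4)
        wide_res = wm.run_collection_from_point(window_scene, 1.0, objective,
                                                100_000, seed=66)
        narrow_res = wm.run_collection_from_point(window_scene, 1.0, narrow,
                                                  100_000, seed=66)
        assert narrow_res.collected_fraction < wide_res.collected_fraction
        qw = surface_spread_quantiles(wide_res, (0.95,))
        qn = surface_spread_quantiles(narrow_res, (0.95,))
        assert qn[0.95] < qw[0.95]


class TestCollectionKernel:
    def test_kernel_mass_integrates_to_efficiency(self, window_scene, objective):
        kern = wm.collection_kernel(
            window_scene, objective, np.array([0.1, 0.5]), 30_000, seed=77,
            r_max=5.6,  # covers the full field of view: no mass is clipped
        )
        np.testing.assert_allclose(kern.mass.sum(axis=1), kern.efficiency, rtol=1e-9)

    def test_surface_kernel_concentrated_at_origin(self, window_scene, objective):
        kern = wm.collection_kernel(
            window_scene, objective, np.array([0.0]), 50_000, seed=78
        )
        within_20um = kern.mass[0, :2].sum() / kern.mass[0].sum()
        assert within_20um > 0.5

    def test_deep_kernel_spreads_beyond_half_millimetre(self, window_scene, objective):
        kern = wm.collection_kernel(
            window_scene, objective, np.array([1.0]), 50_000, seed=79
        )
        r_mid = kern.r_edges[:-1] + 0.005
        beyond = kern.mass[0, r_mid > 0.43].sum() / kern.mass[0].sum()
        assert beyond >= 0.5
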