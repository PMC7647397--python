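import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import widefield_mc as wm
from widefield_mc.engine import run_photons
from widefield_mc.optics import OpticalProperties
from widefield_mc.transport import (
    DepthRecorder,
    NonInteractingMediumError,
    PhotonPacket,
    RandomStream,
    propagate,
    rotate_direction,
    sample_hg_deflection,
    sample_step_length,
)


class TestStepLength:
    def test_closed_form_mean(self):
        # mean free path of grey matter at 480 nm: 1/(0.37 + 11) mm
        rng = np.random.default_rng(0)
        u = rng.random(200_000)
        s = -np.log(u) / wm.GREY_MATTER_480.mu_t
        direct = np.array([sample_step_length(wm.GREY_MATTER_480, x) for x in u[:2000]])
        assert np.allclose(direct, s[:2000])
        assert s.mean() == pytest.approx(1.0 / 11.37, rel=0.01)

    def test_limit_u_to_one(self):
        assert sample_step_length(wm.GREY_MATTER_480, 1 - 1e-12) < 1e-9

    def test_scaling_identity(self):
        p1 = OpticalProperties(0.37, 11.0, 0.89)
        p2 = OpticalProperties(0.74, 22.0, 0.89)
        assert sample_step_length(p1, 0.3) == pytest.approx(
            2.0 * sample_step_length(p2, 0.3)
        )

    def test_non_interacting_signalled(self):
        with pytest.raises(NonInteractingMediumError):
            sample_step_length(OpticalProperties(0.0, 0.0, 0.0), 0.5)


class TestHenyeyGreenstein:
    def test_isotropic_midpoint(self):
        assert sample_hg_deflection(0.0, 0.5) == 0.0

    @pytest.mark.parametrize("g", [0.0, 0.5, 0.89, 0.9])
    def test_mean_cosine_equals_g(self, g):
        rng = np.random.default_rng(12)
        u = rng.random(200_000)
        ct = np.array([sample_hg_deflection(g, x) for x in u])
        se = ct.std() / math.sqrt(u.size)
        assert abs(ct.mean() - g) < 3 * se + 1e-4

    def test_endpoints_bounded(self):
        for u in (1e-12, 1 - 1e-12, 0.25, 0.75):
            assert -1.0 <= sample_hg_deflection(0.89, u) <= 1.0


class TestRotateDirection:
    def test_zero_deflection_identity(self):
        d = np.array([0.6, 0.0, 0.8])
        assert np.allclose(rotate_direction(d, 1.0, 1.23), d, atol=1e-9)

    def test_pole_analytic_case(self):
        out = rotate_direction(np.array([0.0, 0.0, 1.0]), 0.0, 0.0)
        assert np.allclose(out, [1.0, 0.0, 0.0], atol=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(
        st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1),
        st.floats(-1, 1), st.floats(0, 2 * math.pi),
    )
    def test_unit_norm_and_requested_angle(self, a, b, c, ct, phi):
        v = np.array([a, b, c])
        n = np.linalg.norm(v)
        if n < 1e-3:
            return
        v = v / n
        out = rotate_direction(v, ct, phi)
        assert abs(np.linalg.norm(out) - 1.0) < 1e-9
        if abs(v[2]) < 0.9999:  # the polar branch snaps to the z axis
            assert np.dot(out, v) == pytest.approx(ct, abs=1e-7)

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValueError):
            rotate_direction(np.array([1.0, 1.0, 0.0]), 0.5, 0.0)

    def test_scattering_chain_decorrelates_as_g_power_n(self):
        """Composing HG deflections with uniform azimuths gives
        E[cos(angle to the initial axis)] = g^n after n scatters."""
        g = 0.89
        rng = np.random.default_rng(99)
        n_chains, n_steps = 3000, 3
        finals = np.empty(n_chains)
        for i in range(n_chains):
            d = np.array([0.0, 0.0, 1.0])
            for _ in range(n_steps):
                ct = sample_hg_deflection(g, rng.random())
                d = rotate_direction(d, ct, 2 * math.pi * rng.random())
            finals[i] = d[2]
        se = finals.std() / math.sqrt(n_chains)
        assert finals.mean() == pytest.approx(g**n_steps, abs=3.5 * se)


class TestReferencePropagate:
    def test_ballistic_survival_matches_absorption_law(self):
        # mu_s = 0: weight surviving to depth z is exp(-mu_a z)
        scene = wm.build_scene("window").with_grey_matter(
            480, OpticalProperties(0.5, 0.0, 0.0)
        )
        rec = DepthRecorder(pitch=0.01, n_bins=scene.n_depth_bins, radius=2.0)
        tallies = {}
        for i in range(400):
            p = PhotonPacket(position=[0, 0, 1e-9], direction=[0, 0, 1.0])
            propagate(p, scene, RandomStream(500 + i), recorder=rec, tallies=tallies)
            assert p.status in (wm.PhotonStatus.ABSORBED, wm.PhotonStatus.EXITED_BOTTOM)
        z = (np.arange(scene.n_depth_bins) + 0.5) * 0.01
        # pool into 0.2 mm bins before the log fit (avoids the downward
        # bias of log on noisy near-empty bins)
        coarse = rec.fluence[:400].reshape(20, 20).sum(axis=1)
        zc = z[:400].reshape(20, 20).mean(axis=1)
        slope = np.polyfit(zc, np.log(coarse), 1)[0]
        assert slope == pytest.approx(-0.5, rel=0.10)

    def test_weight_accounting_is_exact(self, window_scene):
        tallies = {}
        for i in range(50):
            p = PhotonPacket(position=[0, 0, 0.2], direction=[0, 0, 1.0])
            propagate(p, window_scene, RandomStream(i), tallies=tallies)
        accounted = (
            tallies["deposited"] + tallies["exited_top"] + tallies["exited_lateral"]
            + tallies["exited_bottom"] + tallies["roulette_net"] + tallies["cap_killed"]
        )
        assert accounted == pytest.approx(50.0, abs=1e-9)

    def test_vessel_absorbs_all_weight(self):
        scene = wm.build_scene("vessel-250um")
        # aimed straight down at the vessel from above its apex
        p = PhotonPacket(position=[0, 0, 1e-9], direction=[0, 0, 1.0])
        tallies = {}
        propagate(p, scene, RandomStream(1), wavelength=480, tallies=tallies)
        # the packet cannot cross the absorber: any deposit before entering
        # is interaction-based, and the terminal state is absorption
        assert p.status is wm.PhotonStatus.ABSORBED


class TestKernel:
    def test_energy_conservation(self, small_illumination):
        bal = small_illumination.run.energy_balance()
        assert bal["accounted"] == pytest.approx(bal["launched"], rel=1e-9)
        assert bal["cap_count"] == 0

    def test_determinism_bit_identical(self, window_scene, objective):
        a = wm.run_illumination(window_scene, objective, 5_000, seed=77)
        b = wm.run_illumination(window_scene, objective, 5_000, seed=77)
        assert np.array_equal(a.fluence_z, b.fluence_z)
        assert np.array_equal(a.run.exit_w, b.run.exit_w)
        assert np.array_equal(a.run.exit_x, b.run.exit_x)

    def test_ballistic_depth_profile(self):
        scene = wm.build_scene("window").with_grey_matter(
            480, OpticalProperties(0.37, 0.0, 0.0)
        )
        f = wm.run_illumination(scene, wm.TL2X_SAP, 60_000, seed=5)
        z, prof = wm.depth_profile(f, "surface")
        coarse = prof[:380].reshape(19, 20).sum(axis=1)
        zc = z[:380].reshape(19, 20).mean(axis=1)
        slope = np.polyfit(zc, np.log(coarse), 1)[0]
        assert slope == pytest.approx(-0.37, rel=0.05)

    def test_diffuse_reflectance_matches_h_function(self):
        """Semi-infinite isotropic medium, albedo 0.9, normal incidence:
        exact reflectance 1 - sqrt(0.1) * H(1) = 0.41497 (Chandrasekhar)."""
        scene = wm.LayeredScene(
            volume_radius=50.0, tissue_depth=50.0, coverslip_radius=0.0,
            coverslip_thickness=0.0, skull_thickness=0.0,
            grey_matter={480: OpticalProperties(1.0, 9.0, 0.0),
                         560: OpticalProperties(1.0, 9.0, 0.0)},
        )
        n = 100_000
        pos = np.zeros((n, 3))
        pos[:, 2] = 1e-9
        dirs = np.zeros((n, 3))
        dirs[:, 2] = 1.0
        run = run_photons(scene, 480, pos, dirs, seed=31)
        bal = run.energy_balance()
        r_d = bal["exited_top"] / bal["launched"]
        assert r_d == pytest.approx(0.41497, abs=3 * 0.0016)

    def test_kernel_agrees_with_reference_walker(self):
        """Ballistic transmission through an absorbing slab: compiled
        kernel and the plain-Python walker give the same expectation."""
        scene = wm.build_scene("window").with_grey_matter(
            480, OpticalProperties(1.0, 0.0, 0.0)
        )
        n = 2_000
        pos = np.tile([0.0, 0.0, 1e-9], (n, 1))
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
        run = run_photons(scene, 480, pos, dirs, seed=8)
        bal = run.energy_balance()
        kernel_dep = bal["deposited"] / bal["launched"]
        tallies = {}
        for i in range(500):
            p = PhotonPacket(position=[0, 0, 1e-9], direction=[0, 0, 1.0])
            propagate(p, scene, RandomStream(9000 + i), tallies=tallies)
        ref_dep = tallies["deposited"] / 500
        expected = 1.0 - math.exp(-1.0 * 4.0)  # absorbed within 4 mm of tissue
        assert kernel_dep == pytest.approx(expected, abs=0.02)
        assert ref_dep == pytest.approx(expected, abs=0.05)
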