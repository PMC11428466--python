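import numpy as np
import pytest

from righting import pendulum as pend


class TestLocatePivot:
    def _series(self, point, n=100, noise=0.0, rng=None):
        pos = np.tile(np.asarray(point, float), (n, 1))
        if noise > 0:
            pos = pos + rng.normal(0, noise, pos.shape)
        return pos

    def test_fixed_pivot_recovered_exactly(self):
        lm = {"caudal": self._series([0.0, 0.0, 0.0]),
              "tarsus_L1": self._series([5e-3, 0, 0])}
        contacts = {k: np.ones(100, bool) for k in lm}
        piv = pend.locate_pivot(lm, contacts)
        assert piv.landmark == "caudal"  # body beats foot
        assert np.allclose(piv.point, 0, atol=1e-9)
        assert piv.stationarity < 1e-12

    def test_noisy_pivot_within_noise_scale(self):
        rng = np.random.default_rng(0)
        lm = {"caudal": self._series([1e-3, 2e-3, 0], noise=0.2e-3, rng=rng)}
        contacts = {"caudal": np.ones(100, bool)}
        piv = pend.locate_pivot(lm, contacts)
        assert np.linalg.norm(piv.point - [1e-3, 2e-3, 0]) < 0.2e-3

    def test_airborne_flags_undefined(self):
        lm = {"caudal": self._series([0, 0, 5e-3])}
        contacts = {"caudal": np.zeros(100, bool)}
        with pytest.raises(ValueError, match="contact"):
            pend.locate_pivot(lm, contacts)


class TestOrbitalKinematics:
    def test_circular_motion_rate_recovered(self):
        fps, R, w = 1000.0, 5e-3, 10.0
        t = np.arange(500) / fps
        com = np.column_stack(
            [R * np.cos(w * t), R * np.sin(w * t), np.zeros_like(t)]
        )
        orb = pend.orbital_kinematics(com, np.zeros(3), fps)
        mid = slice(50, -50)
        assert np.allclose(orb["omega_orbital"][mid], w, rtol=0.01)
        assert np.allclose(orb["d"], R)

    def test_stationary_com_zero(self):
        com = np.tile([5e-3, 0, 0], (100, 1))
        orb = pend.orbital_kinematics(com, np.zeros(3), 1000.0)
        assert np.allclose(orb["v_orbital"], 0, atol=1e-12)
        assert np.allclose(orb["omega_orbital"], 0, atol=1e-9)

    def test_d_below_guard_flagged(self):
        com = np.tile([0.5e-3, 0, 0], (50, 1))
        orb = pend.orbital_kinematics(com, np.zeros(3), 1000.0)
        assert np.all(np.isnan(orb["omega_orbital"]))


class TestInertiaAndEnergy:
    def test_point_mass_KE(self):
        M, d, w = 28.4e-6, 4e-3, 30.0
        I, KE = pend.pendulum_inertia_and_KE(0.0, M, d, w)
        assert np.isclose(I, M * d * d)
        assert np.isclose(KE, 0.5 * M * d * d * w * w)

    def test_zero_rate_zero_KE(self):
        _, KE = pend.pendulum_inertia_and_KE(1e-10, 28.4e-6, 4e-3, 0.0)
        assert KE == 0.0

    def test_point_mass_period(self):
        d = 0.1
        T = pend.pendulum_period(28.4e-6 * d * d, 28.4e-6, d)
        assert np.isclose(T, 2 * np.pi * np.sqrt(d / 9.81), rtol=1e-12)
        assert np.isclose(T, 0.6347, atol=5e-4)

    def test_period_scales_sqrt_I(self):
        T1 = pend.pendulum_period(1e-10, 28.4e-6, 4e-3)
        T2 = pend.pendulum_period(2e-10, 28.4e-6, 4e-3)
        assert np.isclose(T2 / T1, np.sqrt(2))

    def test_anchor_scale_period_matches_righting_timescale(self, morph, body_mesh):
        """Standardized-morphology pendulum period ~ tens of ms."""
        from scipy.spatial.transform import Rotation

        from righting import body_model as bm
        from righting.synthetic import SEMI_AXES_DEFAULT, make_reference_pose_library

        body = bm.mesh_mass_properties(body_mesh, 28.4e-6 - morph.total_leg_mass)
        pose = make_reference_pose_library()["planted"]
        R0 = Rotation.from_euler("x", np.pi)
        com_sp = R0.apply(body.com) + [0, 0, SEMI_AXES_DEFAULT[2]]
        axis = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        asm = bm.assemble_anchor(body, R0, com_sp, pose, morph, axis)
        d = 4e-3
        I_pend = asm.I_spin + asm.total_mass * d * d
        T = pend.pendulum_period(I_pend, asm.total_mass, d)
        # a quarter period (tip-over stroke) in the tens-of-ms range
        assert 0.02 < T / 4 < 0.2

    def test_rotation_time_closed_form(self):
        I, tau, theta = 6e-10, 1.5e-6, np.pi
        t = pend.rotation_time(theta, I, tau)
        assert np.isclose(t, np.sqrt(2 * theta * I / tau), rtol=1e-12)


class TestReactionTorque:
    def test_static_balance(self):
        M, r_com = 28.4e-6, 3e-3
        out = pend.reaction_torque_and_force(
            I_pendulum=6e-10, alpha_orbital=0.0, M=M, r_com=r_com,
            r_perp=4e-3, n_tarsi=4,
        )
        assert np.isclose(out["tau_reaction"], M * pend.G * r_com)
        assert np.isclose(out["tau_net"], 0.0)

    def test_apex_zero_arm_zero_reaction(self):
        out = pend.reaction_torque_and_force(
            I_pendulum=6e-10, alpha_orbital=0.0, M=28.4e-6, r_com=0.0,
            r_perp=4e-3, n_tarsi=4,
        )
        assert np.isclose(out["tau_reaction"], 0.0)

    def test_no_feet_flags_force(self):
        out = pend.reaction_torque_and_force(
            I_pendulum=6e-10, alpha_orbital=10.0, M=28.4e-6, r_com=1e-3,
            r_perp=4e-3, n_tarsi=0,
        )
        assert np.isnan(out["F_leg"])
        assert np.isfinite(out["tau_reaction"])

    def test_literal_gravity_arm_option(self):
        common = dict(I_pendulum=6e-10, alpha_orbital=0.0, M=28.4e-6,
                      r_com=2e-3, r_perp=4e-3, n_tarsi=4)
        a = pend.reaction_torque_and_force(**common, gravity_arm="r_com")
        b = pend.reaction_torque_and_force(**common, d=4e-3, gravity_arm="d")
        assert b["tau_reaction"] > a["tau_reaction"]
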