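import numpy as np
import pytest

from righting.synthetic import (
    InstabilityError,
    SyntheticTrialConfig,
    body_landmarks_body_frame,
    make_reference_pose_library,
    simulate_trial,
)


def _ballistic(initial_theta, duration=0.12, **kw):
    cfg = SyntheticTrialConfig(
        mode="pitching", noise_sd=0.0, rigid_legs=True,
        torque_program=[], duration=duration, initial_theta=initial_theta,
        **kw,
    )
    return simulate_trial(cfg)


class TestDynamics:
    def test_balanced_at_apex_stays(self):
        _, probe = _ballistic(0.0, duration=0.005)
        _, truth = _ballistic(probe.theta_apex, duration=0.1)
        assert np.max(np.abs(truth.theta - truth.theta_apex)) < 1e-6
        assert np.ptp(truth.Z_dv) < 1e-5

    def test_ballistic_energy_conserved(self):
        _, probe = _ballistic(0.0, duration=0.005)
        _, truth = _ballistic(probe.theta_apex + np.deg2rad(1), duration=0.25)
        sel = truth.theta < 2.8  # before the body would strike the ground
        E = truth.PE[sel] + truth.KE[sel]
        assert (E.max() - E.min()) / E.mean() < 1e-3

    def test_constant_torque_rotation_time(self):
        tau = 1.5e-6
        cfg = SyntheticTrialConfig(
            mode="pitching", noise_sd=0.0, rigid_legs=True, gravity=0.0,
            torque_program=[(0.0, 10.0, tau)], duration=0.1,
        )
        _, truth = simulate_trial(cfg)
        theta_goal = np.pi / 2
        t_pred = np.sqrt(2 * theta_goal * truth.I_pendulum / tau)
        i = np.argmax(truth.theta >= theta_goal)
        # sub-frame crossing time by linear interpolation
        frac = (theta_goal - truth.theta[i - 1]) / (
            truth.theta[i] - truth.theta[i - 1]
        )
        t_meas = truth.times[i - 1] + frac * (truth.times[i] - truth.times[i - 1])
        assert abs(t_meas - t_pred) / t_pred < 0.01

    def test_runaway_torque_raises(self):
        cfg = SyntheticTrialConfig(
            mode="pitching", noise_sd=0.0, rigid_legs=True, gravity=0.0,
            torque_program=[(0.0, 10.0, 5e-4)], duration=2.0,
        )
        with pytest.raises(InstabilityError):
            simulate_trial(cfg)


class TestTrialGeneration:
    def test_seed_determinism_bit_identical(self):
        a, _ = simulate_trial(SyntheticTrialConfig(seed=42))
        b, _ = simulate_trial(SyntheticTrialConfig(seed=42))
        for name in a.landmarks:
            assert np.array_equal(a.landmarks[name], b.landmarks[name])

    def test_different_seeds_differ(self):
        a, _ = simulate_trial(SyntheticTrialConfig(seed=1))
        b, _ = simulate_trial(SyntheticTrialConfig(seed=2))
        assert not np.allclose(a.landmarks["cranial"], b.landmarks["cranial"])

    def test_noise_free_truth_matches_landmarks(self):
        trial, truth = simulate_trial(
            SyntheticTrialConfig(noise_sd=0.0, seed=0)
        )
        for name in trial.landmarks:
            assert np.array_equal(trial.landmarks[name],
                                  truth.landmarks_clean[name])

    def test_overturned_start_and_righted_end(self):
        for mode in ("diagonal_rotating", "lifted_rotating", "pitching"):
            _, truth = simulate_trial(
                SyntheticTrialConfig(mode=mode, noise_sd=0.0)
            )
            assert truth.Z_dv[0] > 0.99
            assert truth.Z_dv[-1] < -0.5

    def test_failed_mode_never_rights(self):
        _, truth = simulate_trial(
            SyntheticTrialConfig(mode="failed", n_attempts=3, noise_sd=0.0)
        )
        assert np.min(truth.Z_dv) > 0.0
        assert "righted" not in set(truth.phase)

    def test_full_landmark_schema_present(self):
        trial, _ = simulate_trial(SyntheticTrialConfig())
        from righting.io import CANONICAL_LANDMARKS

        assert set(trial.landmarks) == set(CANONICAL_LANDMARKS)


class TestPoseLibrary:
    def test_overturned_supine(self):
        from scipy.spatial.transform import Rotation

        lib = make_reference_pose_library()
        pose = lib["overturned"]
        # dorsal landmark below the cranial-caudal midline: supine
        mid = 0.5 * (pose["cranial"] + pose["caudal"])
        assert pose["dorsum_mid"][2] < mid[2]

    def test_righted_feet_down(self):
        lib = make_reference_pose_library()
        pose = lib["righted"]
        for leg in ("L1", "R1", "L2", "R2", "L3", "R3"):
            assert abs(pose[f"tarsus_{leg}"][2]) < 1e-9
        mid = 0.5 * (pose["cranial"] + pose["caudal"])
        assert pose["dorsum_mid"][2] > mid[2]

    def test_apex_has_max_body_height(self):
        lib = make_reference_pose_library()
        heights = {
            name: 0.5 * (p["cranial"][2] + p["caudal"][2])
            for name, p in lib.items()
        }
        assert max(heights, key=heights.get) == "apex"

    def test_lifted_body_clear_of_ground(self):
        lib = make_reference_pose_library()
        pose = lib["lifted"]
        for name in body_landmarks_body_frame():
            assert pose[name][2] > 1e-3
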