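import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from righting import body_model as bm
from righting.io import LEG_NAMES, TrackedTrial
from righting.synthetic import (
    SEMI_AXES_DEFAULT,
    body_mesh_anatomical,
    make_reference_pose_library,
)


class TestMeshMassProperties:
    def test_unit_cube_inertia(self):
        cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        props = bm.mesh_mass_properties(cube, total_mass=2.0)
        assert np.allclose(props.com, 0, atol=1e-12)
        assert np.allclose(props.inertia_tensor, (2.0 / 6.0) * np.eye(3),
                           atol=1e-9)

    def test_ellipsoid_matches_analytic(self):
        a, b, c = 6e-3, 2e-3, 1.5e-3
        mesh = trimesh.creation.icosphere(subdivisions=5)
        mesh.apply_scale([a, b, c])
        m = 28.4e-6
        props = bm.mesh_mass_properties(mesh, m)
        w = np.sort(props.principal[0])
        # ellipsoid: I_x = m (b^2 + c^2)/5 etc.; fine tessellation -> 0.5%
        expected = np.sort(m / 5.0 * np.array(
            [b * b + c * c, a * a + c * c, a * a + b * b]
        ))
        assert np.all(np.abs(w - expected) / expected < 5e-3)

    def test_translation_invariance_and_tensor_rotation(self):
        mesh = body_mesh_anatomical()
        props = bm.mesh_mass_properties(mesh, 1e-5)
        shifted = mesh.copy()
        shifted.apply_translation([0.01, -0.02, 0.005])
        props2 = bm.mesh_mass_properties(shifted, 1e-5)
        assert np.allclose(props.inertia_tensor, props2.inertia_tensor,
                           rtol=1e-9, atol=1e-22)
        rng = np.random.default_rng(1)
        for _ in range(5):
            R = Rotation.random(random_state=rng).as_matrix()
            rotated = mesh.copy()
            rotated.apply_transform(
                np.block([[R, np.zeros((3, 1))], [np.zeros((1, 3)), 1.0]])
            )
            props3 = bm.mesh_mass_properties(rotated, 1e-5)
            assert np.allclose(
                props3.inertia_tensor, R @ props.inertia_tensor @ R.T,
                rtol=1e-6, atol=1e-18,
            )


class TestRodAndAxes:
    def test_rod_closed_form(self):
        assert np.isclose(bm.rod_inertia(0.012, 1.0), 0.001)
        assert bm.rod_inertia(1.0, 0.0) == 0.0

    def test_rod_matches_point_mass_sum(self):
        m, L = 3.7e-6, 4.4e-3
        n = 10**5
        s = (np.arange(n) + 0.5) / n - 0.5
        brute = np.sum((m / n) * (s * L) ** 2)
        assert abs(bm.rod_inertia(m, L) - brute) / brute < 1e-6

    def test_parallel_axis(self):
        assert bm.parallel_axis(1.2, 3.0, 0.0) == 1.2
        assert np.isclose(bm.parallel_axis(0.0, 2.0, 0.5), 0.5)
        # rod pivoted at its end: mL^2/12 + m (L/2)^2 = mL^2/3
        m, L = 0.01, 0.3
        assert np.isclose(
            bm.parallel_axis(bm.rod_inertia(m, L), m, L / 2), m * L * L / 3
        )

    def test_inertia_about_axis_principal_and_symmetry(self):
        I = np.diag([1.0, 2.0, 3.0])
        assert np.isclose(bm.inertia_about_axis(I, [0, 1, 0]), 2.0)
        r = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        assert np.isclose(
            bm.inertia_about_axis(I, r), bm.inertia_about_axis(I, -r)
        )

    def test_inertia_about_axis_requires_unit_vector(self):
        with pytest.raises(ValueError, match="unit"):
            bm.inertia_about_axis(np.eye(3), [1.0, 1.0, 0.0])

    def test_point_cloud_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(500, 3))
        masses = rng.uniform(0.1, 1.0, 500)
        com = np.average(pts, axis=0, weights=masses)
        rel = pts - com
        I = np.zeros((3, 3))
        for m, p in zip(masses, rel):
            I += m * (np.dot(p, p) * np.eye(3) - np.outer(p, p))
        for _ in range(10):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            d2 = np.sum(rel**2, axis=1) - (rel @ axis) ** 2
            brute = float(np.sum(masses * d2))
            assert abs(bm.inertia_about_axis(I, axis) - brute) / brute < 1e-6


class TestAnchorAssembly:
    def _pose(self, morph):
        lib = make_reference_pose_library()
        return lib["planted"]

    def _body(self, total=28.4e-6, legs_mass=11.2e-6):
        mesh = body_mesh_anatomical()
        return bm.mesh_mass_properties(mesh, total - legs_mass)

    def test_zero_leg_mass_reduces_to_body(self, morph):
        import dataclasses

        from righting.io import LegMorphometrics, RodSegment

        tiny = LegMorphometrics(
            segment_1={leg: RodSegment(3e-3, 1e-15) for leg in LEG_NAMES},
            segment_2={leg: RodSegment(3e-3, 1e-15) for leg in LEG_NAMES},
        )
        body = self._body(legs_mass=0.0)
        pose = self._pose(morph)
        R0 = Rotation.from_euler("x", np.pi)
        com_sp = R0.apply(body.com) + [0, 0, SEMI_AXES_DEFAULT[2]]
        axis = np.array([0.0, 1.0, 0.0])
        asm = bm.assemble_anchor(body, R0, com_sp, pose, tiny, axis)
        I_body_only = bm.inertia_about_axis(
            R0.as_matrix() @ body.inertia_tensor @ R0.as_matrix().T, axis
        )
        assert abs(asm.I_spin - I_body_only) / I_body_only < 1e-6
        assert asm.leg_fraction < 1e-6

    def test_symmetric_pose_com_on_sagittal_plane(self, morph):
        body = self._body()
        pose = self._pose(morph)
        R0 = Rotation.from_euler("x", np.pi)
        com_sp = R0.apply(body.com) + [0, 0, SEMI_AXES_DEFAULT[2]]
        asm = bm.assemble_anchor(
            body, R0, com_sp, pose, morph, np.array([1.0, 0.0, 0.0])
        )
        assert abs(asm.com[1]) < 1e-12

    def test_leg_share_of_spin_inertia_in_observed_band(self, morph):
        """Splayed reference pose: legs carry 65-72% of spin inertia."""
        body = self._body()
        pose = self._pose(morph)
        R0 = Rotation.from_euler("x", np.pi)
        com_sp = R0.apply(body.com) + [0, 0, SEMI_AXES_DEFAULT[2]]
        axis = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        asm = bm.assemble_anchor(body, R0, com_sp, pose, morph, axis)
        assert 0.65 <= asm.leg_fraction <= 0.72

    def test_missing_endpoint_flags_frame(self, morph):
        body = self._body()
        pose = dict(self._pose(morph))
        pose["tarsus_L1"] = np.full(3, np.nan)
        R0 = Rotation.from_euler("x", np.pi)
        com_sp = R0.apply(body.com) + [0, 0, SEMI_AXES_DEFAULT[2]]
        asm = bm.assemble_anchor(
            body, R0, com_sp, pose, morph, np.array([0.0, 1.0, 0.0])
        )
        assert np.isnan(asm.I_spin)

    def test_com_axis_minimizes_parallel_inertia(self, morph):
        body = self._body()
        pose = self._pose(morph)
        R0 = Rotation.from_euler("x", np.pi)
        com_sp = R0.apply(body.com) + [0, 0, SEMI_AXES_DEFAULT[2]]
        axis = np.array([0.0, 1.0, 0.0])
        asm = bm.assemble_anchor(body, R0, com_sp, pose, morph, axis)
        # inertia about any parallel axis exceeds the COM-axis value
        for d in (1e-3, 3e-3):
            shifted = bm.parallel_axis(asm.I_spin, asm.total_mass, d)
            assert shifted > asm.I_spin


class TestStandardScaling:
    def _trial(self, L):
        lm = {"cranial": np.zeros((2, 3)), "caudal": np.zeros((2, 3))}
        lm["cranial"][:, 0] = L
        return TrackedTrial(
            frame_rate=1000.0, times=np.arange(2) / 1000.0,
            landmarks=lm, body_length=L,
        )

    def test_identity_at_standard_length(self):
        trial = self._trial(8.9e-3)
        scaled, f = bm.scale_to_standard(trial)
        assert np.isclose(f, 1.0)
        assert np.allclose(scaled.landmarks["cranial"], trial.landmarks["cranial"])

    def test_fourth_instar_factor(self):
        trial = self._trial(11.7e-3)
        scaled, f = bm.scale_to_standard(trial)
        assert np.isclose(f, 8.9 / 11.7, atol=1e-12)
        assert np.allclose(scaled.landmarks["cranial"][:, 0], 8.9e-3)
        assert scaled.mass == bm.MASS_STANDARD

    def test_idempotent(self):
        trial = self._trial(11.7e-3)
        once, _ = bm.scale_to_standard(trial)
        twice, f2 = bm.scale_to_standard(once)
        assert np.isclose(f2, 1.0)
        assert np.allclose(
            once.landmarks["cranial"], twice.landmarks["cranial"]
        )
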