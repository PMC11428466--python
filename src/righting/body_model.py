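"""Articulated "anchor" mass model: mesh body + twelve rod leg segments.

The body (head, thorax, abdomen) is a single rigid object whose mass
properties come from exact polyhedral volume integrals over a watertight
surface mesh at uniform density.  Each leg is two thin rods (tibia+tarsus
distal, femur+trochanter+coxa proximal) spanned between tracked endpoint
landmarks; rod axial inertia is neglected.  The whole-insect spin moment
of inertia about any axis through the instantaneous COM is composed with
the parallel-axis theorem.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .io import GeometryError, LEG_NAMES, LegMorphometrics, TrackedTrial

__all__ = [
    "MassProperties",
    "mesh_mass_properties",
    "rod_inertia",
    "parallel_axis",
    "inertia_about_axis",
    "rod_inertia_about_axis",
    "AnchorAssembly",
    "assemble_anchor",
    "scale_to_standard",
    "L_BODY_STANDARD",
    "MASS_STANDARD",
]

#: Standardized body length and whole-insect mass used to pool trials
#: across specimens (isometric scaling).
L_BODY_STANDARD = 8.9e-3  # m
MASS_STANDARD = 28.4e-6  # kg


@dataclasses.dataclass
class MassProperties:
    """Mass, COM and inertia tensor (about COM, body axes) of a rigid part."""

    mass: float
    com: np.ndarray
    inertia_tensor: np.ndarray

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float)
        I = np.asarray(self.inertia_tensor, dtype=float)
        if not np.allclose(I, I.T, atol=1e-12 * max(1.0, np.abs(I).max())):
            raise ValueError("inertia tensor must be symmetric")
        self.inertia_tensor = 0.5 * (I + I.T)

    @property
    def principal(self) -> tuple[np.ndarray, np.ndarray]:
        """(principal_moments, principal_axes) — axes as matrix columns."""
        w, v = np.linalg.eigh(self.inertia_tensor)
        return w, v


def mesh_mass_properties(mesh: trimesh.Trimesh, total_mass: float) -> MassProperties:
    """Uniform-density mass properties of a watertight body mesh.

    Uses exact polyhedral volume integrals (divergence-theorem formulas),
    not surface sampling; the tensor is about the COM in mesh axes.
    """
    if total_mass <= 0:
        raise ValueError("total_mass must be positive")
    if not mesh.is_watertight:
        raise GeometryError("mesh must be watertight for volume integrals")
    volume = mesh.volume
    if volume <= 0:
        raise GeometryError("mesh volume must be positive")
    m = mesh.copy()
    m.density = total_mass / volume
    return MassProperties(
        mass=float(total_mass),
        com=np.array(m.center_mass, dtype=float),
        inertia_tensor=np.array(m.moment_inertia, dtype=float),
    )


def rod_inertia(m: float, L: float) -> float:
    """Moment of inertia m L^2 / 12 of a thin rod about a transverse
    axis through its COM."""
    if m < 0 or L < 0:
        raise ValueError("rod mass and length must be non-negative")
    return m * L * L / 12.0


def parallel_axis(I_com: float, mass: float, d: float) -> float:
    """Parallel-axis theorem: I_d = I_com + mass d^2."""
    if d < 0:
        raise ValueError("axis displacement d must be non-negative")
    if mass < 0:
        raise ValueError("mass must be non-negative")
    return I_com + mass * d * d


def inertia_about_axis(I_tensor: np.ndarray, r_hat: np.ndarray) -> float:
    """Scalar moment of inertia r_hat^T I r_hat about a COM axis r_hat.

    ``r_hat`` must already be a unit vector (no silent normalization).
    """
    r_hat = np.asarray(r_hat, dtype=float)
    if not np.isclose(np.linalg.norm(r_hat), 1.0, atol=1e-9):
        raise ValueError("axis must be a unit vector")
    I = np.asarray(I_tensor, dtype=float)
    if not np.allclose(I, I.T, atol=1e-9 * max(1.0, np.abs(I).max())):
        raise ValueError("inertia tensor must be symmetric")
    return float(r_hat @ I @ r_hat)


def rod_inertia_about_axis(
    m: float, p1: np.ndarray, p2: np.ndarray, point: np.ndarray, axis: np.ndarray
) -> float:
    """Inertia of a thin rod from p1 to p2 about an arbitrary axis.

    The axis passes through ``point`` with unit direction ``axis``.  The
    rod's own transverse inertia is reduced by the component of the rod
    direction along the axis (axial inertia of a thin rod is zero), then
    the parallel-axis theorem moves it from the rod COM to the axis using
    the perpendicular distance.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    u = p2 - p1
    L = np.linalg.norm(u)
    u = u / L if L > 0 else np.zeros(3)
    cos2 = float(u @ axis) ** 2
    I_com = rod_inertia(m, L) * (1.0 - cos2)
    com = 0.5 * (p1 + p2)
    rel = com - np.asarray(point, float)
    d_perp = np.linalg.norm(rel - (rel @ axis) * axis)
    return parallel_axis(I_com, m, d_perp)


#: leg segment endpoint landmark names: segment_1 distal (femur_tibia ->
#: tarsus), segment_2 proximal (coxa -> femur_tibia)
def _segment_endpoints(leg: str) -> dict[str, tuple[str, str]]:
    return {
        "segment_1": (f"femur_tibia_{leg}", f"tarsus_{leg}"),
        "segment_2": (f"coxa_{leg}", f"femur_tibia_{leg}"),
    }


@dataclasses.dataclass
class AnchorAssembly:
    """Whole-insect composition at one frame."""

    com: np.ndarray  # whole-insect COM, spatial frame, m
    com_body: np.ndarray
    total_mass: float
    I_spin: float  # spin inertia about `axis` through whole COM, kg m^2
    I_spin_body: float
    I_spin_legs: float
    leg_fraction: float  # I_spin_legs / I_spin
    axis: np.ndarray


def assemble_anchor(
    body: MassProperties,
    body_rotation: Rotation,
    body_com_spatial: np.ndarray,
    leg_landmarks: dict[str, np.ndarray],
    morph: LegMorphometrics,
    axis: np.ndarray,
) -> AnchorAssembly:
    """Compose body + 12 rod segments into whole-insect COM and spin inertia.

    Parameters
    ----------
    body : MassProperties
        Mesh mass properties in the body frame.
    body_rotation : scipy Rotation
        Body->spatial rotation at this frame.
    body_com_spatial : (3,)
        Body COM position in the spatial frame at this frame.
    leg_landmarks : dict
        Spatial positions of ``coxa_*``, ``femur_tibia_*`` and
        ``tarsus_*`` landmarks at this frame; a segment with any NaN
        endpoint is treated per its morphometric mass placed at the
        available endpoint is *not* attempted — the frame output is NaN.
    axis : (3,) unit vector
        Spin axis direction (spatial frame).

    Returns an :class:`AnchorAssembly`; if any required endpoint is
    missing the numeric fields are NaN (flagged, not an exception).
    """
    axis = np.asarray(axis, dtype=float)
    if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-9):
        raise ValueError("axis must be a unit vector")
    body_com_spatial = np.asarray(body_com_spatial, dtype=float)

    segments = []  # (mass, p1, p2)
    for leg in LEG_NAMES:
        eps = _segment_endpoints(leg)
        for seg_name, (n1, n2) in eps.items():
            seg = getattr(morph, seg_name)[leg]
            p1 = leg_landmarks.get(n1)
            p2 = leg_landmarks.get(n2)
            if (
                p1 is None
                or p2 is None
                or not np.all(np.isfinite(p1))
                or not np.all(np.isfinite(p2))
            ):
                nan = np.full(3, np.nan)
                return AnchorAssembly(
                    com=nan, com_body=body_com_spatial,
                    total_mass=body.mass + morph.total_leg_mass,
                    I_spin=np.nan, I_spin_body=np.nan, I_spin_legs=np.nan,
                    leg_fraction=np.nan, axis=axis,
                )
            segments.append((seg.mass, np.asarray(p1, float), np.asarray(p2, float)))

    total_mass = body.mass + sum(m for m, _, _ in segments)
    com = body.mass * body_com_spatial
    for m, p1, p2 in segments:
        com = com + m * 0.5 * (p1 + p2)
    com = com / total_mass

    # body: rotate tensor to spatial axes, Eq-4 projection, parallel axis
    R = body_rotation.as_matrix()
    I_body_spatial = R @ body.inertia_tensor @ R.T
    I_body_com = inertia_about_axis(I_body_spatial, axis)
    rel = body_com_spatial - com
    d_perp = np.linalg.norm(rel - (rel @ axis) * axis)
    I_body = parallel_axis(I_body_com, body.mass, d_perp)

    I_legs = 0.0
    for m, p1, p2 in segments:
        I_legs += rod_inertia_about_axis(m, p1, p2, com, axis)

    I_total = I_body + I_legs
    return AnchorAssembly(
        com=com,
        com_body=body_com_spatial,
        total_mass=total_mass,
        I_spin=I_total,
        I_spin_body=I_body,
        I_spin_legs=I_legs,
        leg_fraction=I_legs / I_total if I_total > 0 else np.nan,
        axis=axis,
    )


def scale_to_standard(
    trial: TrackedTrial,
    L_std: float = L_BODY_STANDARD,
    M_std: float = MASS_STANDARD,
) -> tuple[TrackedTrial, float]:
    """Rescale tracked coordinates to the standardized body length.

    Every coordinate is multiplied by ``L_std / body_length`` so pooled
    trials share one morphology; the mass is set to the standardized
    whole-insect mass.  Returns the scaled trial and the scale factor.
    Idempotent after the first application.
    """
    if trial.body_length is None or not trial.body_length > 0:
        raise ValueError("trial.body_length must be set and positive")
    factor = L_std / trial.body_length
    scaled = trial.copy()
    for name in scaled.landmarks:
        scaled.landmarks[name] = scaled.landmarks[name] * factor
    scaled.body_length = L_std
    scaled.mass = M_std
    scaled.meta["scale_factor"] = factor
    return scaled, factor
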