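"""Rigid-body attitude and angular kinematics from landmark trajectories.

Attitude is the rotation taking the anatomical body frame (x cranial,
y lateral, z dorsal) into the laboratory spatial frame (Z vertical up).
It is represented internally as a unit quaternion (scalar-first,
body->spatial) to avoid Euler-angle singularities; Tait-Bryan z-y'-x''
(yaw, pitch, roll) angles are derived for reporting.  The orientation
summary statistic is Z_dv, the Z-component of the unit dorsal->ventral
body axis: +1 supine (overturned flat on the back), 0 at the flipping
point, -1 fully upright.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

from .io import GeometryError, TrackedTrial
from .smoothing import derivative, smooth_series

__all__ = [
    "Attitude",
    "GroundPlane",
    "fit_ground_plane",
    "estimate_attitude",
    "angular_velocity",
    "compute_Zdv",
    "euler_from_quaternion",
    "quaternion_from_euler",
    "anatomical_frame",
    "reference_configuration",
    "attitude_series",
    "KinematicSeries",
    "compute_kinematics",
]

#: Dorsal->ventral unit axis in the body frame (z is dorsal).
DV_AXIS_BODY = np.array([0.0, 0.0, -1.0])


@dataclasses.dataclass
class Attitude:
    """Body->spatial rotation plus translation of the body origin."""

    quaternion: np.ndarray  # scalar-first unit quaternion
    translation: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3)
    )

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternion, dtype=float)
        norm = np.linalg.norm(q)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError(f"quaternion norm {norm} != 1")
        self.quaternion = q / norm
        self.translation = np.asarray(self.translation, dtype=float)

    @property
    def rotation(self) -> Rotation:
        w, x, y, z = self.quaternion
        return Rotation.from_quat([x, y, z, w])

    @property
    def euler(self) -> tuple[float, float, float]:
        """(yaw, pitch, roll) in rad, intrinsic Tait-Bryan z-y'-x''."""
        return euler_from_quaternion(self.quaternion)

    def apply(self, points_body: np.ndarray) -> np.ndarray:
        """Map body-frame points into the spatial frame."""
        return self.rotation.apply(points_body) + self.translation


def _quat_scalar_first(rot: Rotation) -> np.ndarray:
    x, y, z, w = rot.as_quat()
    q = np.array([w, x, y, z])
    return -q if w < 0 else q


def euler_from_quaternion(q) -> tuple[float, float, float]:
    """Intrinsic z-y'-x'' (yaw, pitch, roll) angles of a unit quaternion.

    At gimbal lock (|pitch| = pi/2) roll is set to 0 and the remaining
    freedom folded into yaw.
    """
    w, x, y, z = np.asarray(q, dtype=float)
    rot = Rotation.from_quat([x, y, z, w])
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            yaw, pitch, roll = rot.as_euler("ZYX")
    # scipy zeroes the *first* angle at lock for intrinsic sequences; we
    # want roll = 0 with the freedom in yaw, so recompute explicitly.
    if abs(abs(pitch) - np.pi / 2) < 1e-9:
        R = rot.as_matrix()
        pitch = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
        # with pitch = +-pi/2 and roll := 0: R[0,1] = -s_yaw*sign, etc.
        yaw = np.arctan2(-R[0, 1], R[1, 1])
        roll = 0.0
    return float(yaw), float(pitch), float(roll)


def quaternion_from_euler(yaw: float, pitch: float, roll: float) -> np.ndarray:
    """Inverse of :func:`euler_from_quaternion` (scalar-first output)."""
    rot = Rotation.from_euler("ZYX", [yaw, pitch, roll])
    return _quat_scalar_first(rot)


@dataclasses.dataclass(frozen=True)
class GroundPlane:
    """Plane n.x = offset with unit normal oriented toward +Z."""

    normal: np.ndarray
    offset: float
    residual_sd: float

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.normal - self.offset

    def project(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal projection of points onto the plane (3D coords)."""
        d = self.signed_distance(points)
        return np.asarray(points) - np.outer(d, self.normal)

    def to_plane_coords(self, points: np.ndarray) -> np.ndarray:
        """2D coordinates of projected points in an in-plane basis."""
        n = self.normal
        u = np.cross([0.0, 0.0, 1.0], n)
        if np.linalg.norm(u) < 1e-12:
            u = np.array([1.0, 0.0, 0.0])
        else:  # pragma: no cover - tilted calibration
            u /= np.linalg.norm(u)
        v = np.cross(n, u)
        p = self.project(np.atleast_2d(points))
        return np.stack([p @ u, p @ v], axis=-1)


def fit_ground_plane(points: np.ndarray) -> GroundPlane:
    """Total-least-squares plane through foot-contact points.

    The normal is the singular vector of the centred cloud with smallest
    singular value, oriented toward positive Z; the residual SD along the
    normal is reported (tracking in this kind of setup resolves the
    ground to a few tenths of a mm).
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if pts.shape[0] < 3:
        raise GeometryError("need >= 3 finite points to fit a plane")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise GeometryError("points are collinear; plane is degenerate")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    resid = (pts - centroid) @ normal
    return GroundPlane(
        normal=normal,
        offset=float(centroid @ normal),
        residual_sd=float(np.sqrt(np.mean(resid**2))),
    )


def estimate_attitude(
    reference_config: np.ndarray, observed_config: np.ndarray
) -> Attitude:
    """Least-squares rigid rotation+translation (no scaling), Kabsch style.

    ``reference_config`` holds landmark positions in the body frame,
    ``observed_config`` the matching positions in the spatial frame; rows
    with NaN in either set are dropped.
    """
    ref = np.asarray(reference_config, dtype=float)
    obs = np.asarray(observed_config, dtype=float)
    ok = np.all(np.isfinite(ref), axis=1) & np.all(np.isfinite(obs), axis=1)
    ref, obs = ref[ok], obs[ok]
    if ref.shape[0] < 3:
        raise GeometryError("need >= 3 common landmarks for attitude")
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-12) < 2:
        raise GeometryError("landmark configuration is degenerate")
    rot, _ = Rotation.align_vectors(obs - obs.mean(axis=0), ref_c)
    t = obs.mean(axis=0) - rot.apply(ref.mean(axis=0))
    return Attitude(quaternion=_quat_scalar_first(rot), translation=t)


def angular_velocity(att1: Attitude, att2: Attitude, dt: float):
    """Finite-rotation angular velocity between two attitudes.

    The relative rotation q2*q1^-1 (spatial frame) is decomposed into
    axis r_hat and angle dtheta in [0, pi]; omega = (dtheta/dt) r_hat.

    Returns
    -------
    omega : (3,) rad/s,  r_hat : (3,) unit axis,  dtheta : rad
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rel = att2.rotation * att1.rotation.inv()
    rotvec = rel.as_rotvec()
    dtheta = float(np.linalg.norm(rotvec))
    r_hat = rotvec / dtheta if dtheta > 0 else np.zeros(3)
    return rotvec / dt, r_hat, dtheta


def compute_Zdv(attitude: Attitude) -> float:
    """Z-component of the unit dorsal->ventral axis in the spatial frame."""
    return float(attitude.rotation.apply(DV_AXIS_BODY)[2])


def anatomical_frame(cranial, caudal, dorsum_mid, ventral_ref=None):
    """Orthonormal body axes from anatomical landmarks.

    Returns (R, origin): columns of R are the body x (cranial), y
    (lateral) and z (dorsal) axes in the spatial frame; origin is the
    cranial-caudal midpoint.  The dorsal direction is taken from the
    dorsal midline point relative to ``ventral_ref`` (e.g. the mean
    coxa position) when given — a much longer, better-conditioned
    baseline than the offset from the cranial-caudal axis alone.
    """
    cranial = np.asarray(cranial, float)
    caudal = np.asarray(caudal, float)
    dorsum = np.asarray(dorsum_mid, float)
    x = cranial - caudal
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise GeometryError("cranial and caudal landmarks coincide")
    x /= nx
    origin = 0.5 * (cranial + caudal)
    base = origin if ventral_ref is None else np.asarray(ventral_ref, float)
    d = dorsum - base
    d -= (d @ x) * x
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise GeometryError("dorsal landmark lies on the cranial-caudal axis")
    z = d / nd
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=1), origin


def reference_configuration(
    trial: TrackedTrial, names: list[str], n_frames: int = 5
) -> np.ndarray:
    """Body-frame reference landmark geometry.

    The mean geometry of the first ``n_frames`` frames with all three
    anatomical axis landmarks valid is expressed in the anatomical frame,
    so that attitude estimates are anchored to the upright reference
    orientation regardless of the trial's starting pose.
    """
    need = ("cranial", "caudal", "dorsum_mid")
    valid = np.all(
        [np.all(np.isfinite(trial.landmarks[n]), axis=1) for n in need], axis=0
    )
    idx = np.flatnonzero(valid)[:n_frames]
    if idx.size == 0:
        raise GeometryError("no frames with valid axis landmarks")
    mean = {n: np.nanmean(trial.landmarks[n][idx], axis=0) for n in names}
    coxae = [mean[n] for n in names if n.startswith("coxa_")]
    ventral = np.mean(coxae, axis=0) if len(coxae) >= 2 else None
    R, origin = anatomical_frame(
        mean["cranial"], mean["caudal"], mean["dorsum_mid"], ventral_ref=ventral
    )
    return np.stack([(mean[n] - origin) @ R for n in names])


def attitude_series(
    trial: TrackedTrial, landmark_names: list[str] | None = None
) -> list[Attitude | None]:
    """Per-frame attitude from rigid registration of body landmarks.

    Quaternion hemisphere continuity is enforced along the series (the
    sign is flipped whenever q . q_prev < 0).
    """
    if landmark_names is None:
        # all rigidly body-fixed landmarks present in the trial
        landmark_names = [
            n
            for n in trial.landmarks
            if n in ("cranial", "caudal", "dorsum_mid")
            or n.startswith("coxa_")
        ]
    ref = reference_configuration(trial, landmark_names)
    obs_all = trial.landmark_array(landmark_names)
    out: list[Attitude | None] = []
    q_prev = None
    for i in range(trial.n_frames):
        try:
            att = estimate_attitude(ref, obs_all[i])
        except GeometryError:
            out.append(None)
            continue
        if q_prev is not None and att.quaternion @ q_prev < 0:
            att = Attitude(-att.quaternion, att.translation)
        q_prev = att.quaternion
        out.append(att)
    return out


@dataclasses.dataclass
class KinematicSeries:
    """Per-frame smoothed pose and angular kinematics of one trial."""

    times: np.ndarray
    frame_rate: float
    quaternions: np.ndarray  # (n, 4) scalar-first, NaN rows where missing
    translations: np.ndarray  # (n, 3) body origin in spatial frame
    euler: np.ndarray  # (n, 3) yaw, pitch, roll
    Z_dv: np.ndarray
    omega: np.ndarray  # (n, 3) rad/s, spatial frame
    omega_spin_rp: np.ndarray  # (n,) roll+pitch spin magnitude
    alpha: np.ndarray  # (n, 3) rad/s^2
    landmarks_smooth: dict[str, np.ndarray]

    @property
    def n_frames(self) -> int:
        return self.times.size

    def attitude(self, i: int) -> Attitude | None:
        q = self.quaternions[i]
        if not np.all(np.isfinite(q)):
            return None
        return Attitude(q, self.translations[i])


def compute_kinematics(
    trial: TrackedTrial,
    body_window_ms: float = 25.0,
    leg_window_ms: float = 5.0,
    robust: bool = True,
) -> KinematicSeries:
    """Smooth landmarks and derive attitude, Z_dv, omega and alpha.

    Body landmarks are smoothed with the long window, leg landmarks with
    the short one.  Angular velocity uses central finite rotations of the
    attitude series; angular acceleration differentiates omega with the
    body window.
    """
    n = trial.n_frames
    smooth_lm: dict[str, np.ndarray] = {}
    for name, xyz in trial.landmarks.items():
        win = leg_window_ms if ("tarsus" in name or "femur" in name) else body_window_ms
        smooth_lm[name] = smooth_series(
            xyz, trial.frame_rate, window_ms=win, robust=robust,
            times=trial.times,
        )
    smooth_trial = TrackedTrial(
        frame_rate=trial.frame_rate,
        times=trial.times,
        landmarks=smooth_lm,
        substrate=trial.substrate,
        instar=trial.instar,
        body_length=trial.body_length,
        mass=trial.mass,
        meta=dict(trial.meta),
    )
    atts = attitude_series(smooth_trial)
    quats = np.full((n, 4), np.nan)
    trans = np.full((n, 3), np.nan)
    for i, att in enumerate(atts):
        if att is None:
            continue
        quats[i] = att.quaternion
        trans[i] = att.translation
    # orientation is smoothed like the coordinates: quaternion
    # components (hemisphere-continuous) are locally regressed and
    # renormalized, which suppresses frame-to-frame registration noise
    # before differentiation
    quats = smooth_series(
        quats, trial.frame_rate, window_ms=body_window_ms, robust=robust,
        times=trial.times,
    )
    norms = np.linalg.norm(quats, axis=1)
    ok = np.isfinite(norms) & (norms > 0)
    quats[ok] /= norms[ok, None]
    atts = [
        Attitude(quats[i], trans[i]) if ok[i] and np.all(np.isfinite(trans[i]))
        else None
        for i in range(n)
    ]
    euler = np.full((n, 3), np.nan)
    zdv = np.full(n, np.nan)
    for i, att in enumerate(atts):
        if att is None:
            continue
        euler[i] = att.euler
        zdv[i] = compute_Zdv(att)
    omega = np.full((n, 3), np.nan)
    dt = 1.0 / trial.frame_rate
    for i in range(n):
        j, k = max(0, i - 1), min(n - 1, i + 1)
        if j == k:
            continue
        a1, a2 = atts[j], atts[k]
        if a1 is None or a2 is None:
            continue
        w, _, _ = angular_velocity(a1, a2, (k - j) * dt)
        omega[i] = w
    alpha = derivative(omega, trial.frame_rate, window_ms=body_window_ms,
                       times=trial.times)
    omega_rp = np.full(n, np.nan)
    for i, att in enumerate(atts):
        if att is None or not np.all(np.isfinite(omega[i])):
            continue
        R = att.rotation.as_matrix()  # columns: body axes in spatial frame
        wx = omega[i] @ R[:, 0]
        wy = omega[i] @ R[:, 1]
        omega_rp[i] = np.hypot(wx, wy)
    return KinematicSeries(
        times=trial.times,
        frame_rate=trial.frame_rate,
        quaternions=quats,
        translations=trans,
        euler=euler,
        Z_dv=zdv,
        omega=omega,
        omega_spin_rp=omega_rp,
        alpha=alpha,
        landmarks_smooth=smooth_lm,
    )
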