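"""Synthetic righting trials with exact ground truth.

The generator emulates the study conditions: a rigid flattened
(ellipsoidal) body rotating about a fixed ground pivot as an inverted
physical pendulum, six articulated two-segment legs following prescribed
stance/swing programs, landmarks sampled at 1000 fps with mm-scale
Gaussian observation noise, and the three righting modes (diagonal
rotating, lifted rotating, pitching) plus programmed failed attempts.

Dynamics integrate the pivoted rotation theta about a fixed horizontal
axis with a 4th-order fixed-step Runge-Kutta scheme at the sampling
rate:  I_pend theta'' = tau_applied + tau_gravity(theta) - c theta'.
The pendulum inertia is that of the body plus the legs frozen in their
starting pose; legs are kinematically prescribed, not force-coupled.
Ground truth (attitude, omega, COM, PE, KE, torque, phase labels) is
stored noise-free alongside the noisy landmark observations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .body_model import (
    MASS_STANDARD,
    MassProperties,
    assemble_anchor,
    mesh_mass_properties,
)
from .io import LEG_NAMES, LegMorphometrics, TrackedTrial, default_morphometrics
from .pendulum import G as G_DEFAULT

__all__ = [
    "SyntheticTrialConfig",
    "GroundTruth",
    "simulate_trial",
    "ellipsoid_mesh",
    "body_landmarks_body_frame",
    "make_reference_pose_library",
    "InstabilityError",
]

#: default ellipsoid semi-axes, ~ standardized L_body/2 and a flattened
#: dorsoventral profile
SEMI_AXES_DEFAULT = (4.45e-3, 1.8e-3, 1.1e-3)

MODES = ("diagonal_rotating", "lifted_rotating", "pitching", "failed")

_OMEGA_LIMIT = 1e3  # rad/s; integrator instability guard


class InstabilityError(RuntimeError):
    """The programmed torque drove the integrator past the rate limit."""


def ellipsoid_mesh(semi_axes=SEMI_AXES_DEFAULT, subdivisions: int = 3) -> trimesh.Trimesh:
    """Watertight triangulated ellipsoid (synthetic body stand-in)."""
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions)
    mesh.apply_scale(np.asarray(semi_axes, float))
    return mesh


def body_mesh_anatomical(semi_axes=SEMI_AXES_DEFAULT, subdivisions: int = 3) -> trimesh.Trimesh:
    """Ellipsoid body mesh expressed in the anatomical analysis frame.

    The analysis pipeline's body frame has its origin at the
    cranial-caudal landmark midpoint; body meshes handed to
    ``analyze_trial`` must use that convention.  For the synthetic
    landmark layout this midpoint sits 0.8 c dorsal of the ellipsoid
    centre.
    """
    mesh = ellipsoid_mesh(semi_axes, subdivisions)
    mesh.apply_translation([0.0, 0.0, -0.8 * semi_axes[2]])
    return mesh


def body_landmarks_body_frame(semi_axes=SEMI_AXES_DEFAULT) -> dict[str, np.ndarray]:
    """Rigid body-fixed landmarks (body frame: x cranial, z dorsal).

    cranial/caudal sit on the dorsal shoulder of the ellipsoid so that
    they lie near the ground when the insect is overturned; coxae are
    ventro-lateral.
    """
    a, b, c = semi_axes
    lm = {
        "cranial": np.array([0.9 * a, 0.0, 0.8 * c]),
        "caudal": np.array([-0.9 * a, 0.0, 0.8 * c]),
        "dorsum_mid": np.array([0.0, 0.0, c]),
    }
    coxa_x = {"1": 0.5 * a, "2": 0.05 * a, "3": -0.45 * a}
    for leg in LEG_NAMES:
        side = 1.0 if leg[0] == "L" else -1.0
        lm[f"coxa_{leg}"] = np.array(
            [coxa_x[leg[1]], side * 0.85 * b, -0.4 * c]
        )
    return lm


@dataclasses.dataclass
class SyntheticTrialConfig:
    """Fully determines a generated trial plus its ground truth."""

    mode: str = "diagonal_rotating"
    semi_axes: tuple[float, float, float] = SEMI_AXES_DEFAULT
    total_mass: float = MASS_STANDARD  # kg, split body/legs per morphometrics
    morphometrics: LegMorphometrics | None = None
    frame_rate: float = 1000.0  # fps
    noise_sd: float = 0.2e-3  # m, per coordinate
    seed: int = 0
    n_attempts: int = 1  # total attempts; the last succeeds unless mode='failed'
    torque: float = 1.5e-6  # N m, applied during the push phase
    damping: float = 5e-9  # N m s, active while coasting back
    gravity: float = G_DEFAULT  # m/s^2; 0 isolates the applied torque
    lift_height: float = 2.5e-3  # m, body clearance in lifted_rotating
    theta_final: float = 2.5  # rad, rest angle after tip-over
    swing_amplitude: float = 2.0e-3  # m, leg swing z amplitude (0 = rigid)
    swing_frequency: float = 10.0  # Hz
    rigid_legs: bool = False  # freeze all legs to the body (exact rigid body)
    torque_program: list[tuple[float, float, float]] | None = None
    #: with an explicit torque_program the behavioural controller is
    #: bypassed: no clamping, no damping phases, no attempts
    initial_theta: float = 0.0
    initial_theta_dot: float = 0.0
    duration: float | None = None  # s; required for torque_program runs

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.morphometrics is None:
            self.morphometrics = default_morphometrics()


@dataclasses.dataclass
class GroundTruth:
    """Noise-free per-frame truth for a simulated trial."""

    times: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    omega_orbital: np.ndarray  # |theta_dot|
    Z_dv: np.ndarray
    quaternions: np.ndarray  # (n, 4) scalar-first body->spatial
    com: np.ndarray  # (n, 3) whole-insect (frozen-leg) COM
    PE: np.ndarray  # J, M g z_com
    KE: np.ndarray  # J, 1/2 I_pend theta_dot^2
    tau_applied: np.ndarray  # N m
    phase: np.ndarray  # per-frame label strings
    I_pendulum: float
    I_spin_com: float
    leg_fraction: float
    pivot: np.ndarray  # axis point (on the rotation axis)
    axis: np.ndarray  # unit rotation axis, spatial frame
    mode: str
    n_attempts: int
    landmarks_clean: dict[str, np.ndarray]
    theta_apex: float


def _mode_geometry(cfg: SyntheticTrialConfig, lm_body: dict[str, np.ndarray]):
    """Rotation axis, axis point, base height and stance foot layout."""
    a, b, c = cfg.semi_axes
    R0 = Rotation.from_euler("x", np.pi)  # overturned: roll 180 deg
    h0 = c  # body centre height with the dorsum resting on the ground
    caudal_spatial = R0.apply(lm_body["caudal"]) + np.array([0, 0, h0])
    diag = np.array([-1.0, -1.0, 0.0]) / np.sqrt(2.0)
    mm = 1e-3
    if cfg.mode == "pitching":
        axis = np.array([0.0, -1.0, 0.0])
        pivot = caudal_spatial
        stance = {
            "L3": np.array([-4.5, 2.0, 0.0]) * mm,
            "R3": np.array([-4.5, -2.0, 0.0]) * mm,
        }
        swing = ("L1", "R1", "L2", "R2")
        lift = 0.0
    elif cfg.mode == "lifted_rotating":
        # opposite handedness: the pivot sits on the stance side, so the
        # positive rotation that lifts the COM is about +xy-diagonal
        axis = -diag
        lift = cfg.lift_height
        pivot = np.array([0.0, -2.5 * mm, lift])
        stance = {
            "R1": np.array([3.0, -2.5, 0.0]) * mm,
            "R2": np.array([0.0, -3.0, 0.0]) * mm,
            "R3": np.array([-3.0, -2.5, 0.0]) * mm,
        }
        swing = ("L1", "L2", "L3")
    else:  # diagonal_rotating and failed
        axis = diag
        pivot = caudal_spatial
        # four corners enclosing the whole COM ground track of the stroke
        stance = {
            "R1": np.array([4.6, -4.6, 0.0]) * mm,
            "R2": np.array([4.6, 4.6, 0.0]) * mm,
            "R3": np.array([-4.6, -4.6, 0.0]) * mm,
            "L3": np.array([-4.6, 4.6, 0.0]) * mm,
        }
        swing = ("L1", "L2")
        lift = 0.0
    return R0, h0, axis, pivot, stance, swing, lift


def _body_mass_split(cfg: SyntheticTrialConfig) -> float:
    return cfg.total_mass - cfg.morphometrics.total_leg_mass


def _leg_positions_t0(cfg, R0, h0, lm_body, stance, lift):
    """Leg landmark positions at t = 0 (theta = 0, before any lift)."""
    shift = np.array([0.0, 0.0, h0])
    leg_lm = {}
    for leg in LEG_NAMES:
        coxa = R0.apply(lm_body[f"coxa_{leg}"]) + shift
        if leg in stance:
            tarsus = np.asarray(stance[leg], float).copy()
        else:
            s = np.sign(lm_body[f"coxa_{leg}"][1])
            off_body = np.array([0.0, s * 1.5e-3, _swing_z(cfg, leg, 0.0) - 1.5e-3])
            tarsus = coxa + R0.apply(off_body)
        joint = 0.5 * (coxa + tarsus) + np.array([0.0, 0.0, 0.5e-3])
        leg_lm[f"coxa_{leg}"] = coxa
        leg_lm[f"tarsus_{leg}"] = tarsus
        leg_lm[f"femur_tibia_{leg}"] = joint
    return leg_lm


def _frozen_assembly(cfg, body_props, R0, h0, lm_body, stance, lift, axis):
    """Whole-insect COM and spin inertia with legs frozen at t = 0."""
    leg_lm = {
        k: v + np.array([0.0, 0.0, lift])
        for k, v in _leg_positions_t0(cfg, R0, h0, lm_body, stance, lift).items()
    }
    body_com_spatial = R0.apply(body_props.com) + np.array([0.0, 0.0, h0 + lift])
    asm = assemble_anchor(
        body_props, R0, body_com_spatial, leg_lm, cfg.morphometrics, axis
    )
    return asm, leg_lm


def _theta_apex(com0, pivot, axis):
    """Angle at which the rotating COM passes directly over the axis."""
    r = com0 - pivot
    r_par = (r @ axis) * axis
    r_perp = r - r_par
    w = np.cross(axis, r_perp)
    # z(theta) = const + cos(theta) r_perp_z + sin(theta) w_z; apex at max z
    return float(np.mod(np.arctan2(w[2], r_perp[2]), 2 * np.pi))


def _swing_z(cfg, leg, t):
    """Prescribed body-frame tarsus z-excursion for a swinging leg.

    Phase offsets and per-leg second harmonics keep fore/mid pairs
    strongly but imperfectly correlated, as in real righting strokes.
    """
    A = cfg.swing_amplitude
    f = cfg.swing_frequency
    phase = {"L1": 0.0, "R1": 0.45 * np.pi, "L2": 0.55 * np.pi,
             "R2": 1.0 * np.pi, "L3": 0.3 * np.pi, "R3": 1.3 * np.pi}[leg]
    h2 = {"L1": 0.15, "R1": 0.35, "L2": 0.30, "R2": 0.20,
          "L3": 0.25, "R3": 0.25}[leg]
    w = 2 * np.pi * f
    return A * (np.sin(w * t + phase) + h2 * np.sin(2 * w * t + 2.7 * phase))


def simulate_trial(cfg: SyntheticTrialConfig) -> tuple[TrackedTrial, GroundTruth]:
    """Generate one synthetic righting trial plus its ground truth.

    Without an explicit ``torque_program`` a behavioural controller
    produces ``n_attempts`` righting attempts: each push applies the
    configured torque until a target angle, failed attempts coast back
    under damping to the overturned rest, and the final attempt (unless
    ``mode='failed'``) passes the apex and settles upright with all feet
    planted.  Identical configs and seeds give bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    lm_body = body_landmarks_body_frame(cfg.semi_axes)
    mesh = ellipsoid_mesh(cfg.semi_axes)
    body_mass = _body_mass_split(cfg)
    if body_mass <= 0:
        raise ValueError("leg masses exceed total mass")
    body_props = mesh_mass_properties(mesh, body_mass)
    R0, h0, axis, pivot, stance, swing, lift = _mode_geometry(cfg, lm_body)

    asm, leg_lm0 = _frozen_assembly(
        cfg, body_props, R0, h0, lm_body, stance, lift, axis
    )
    com0 = asm.com
    M = asm.total_mass
    r = com0 - pivot
    r_perp = r - (r @ axis) * axis
    d_perp = np.linalg.norm(r_perp)
    I_pend = asm.I_spin + M * d_perp**2
    theta_apex = _theta_apex(com0, pivot, axis)

    dt = 1.0 / cfg.frame_rate
    g = cfg.gravity

    def tau_gravity(theta):
        Rt = Rotation.from_rotvec(axis * theta)
        com_t = pivot + Rt.apply(r)
        return float(np.cross(com_t - pivot, [0.0, 0.0, -M * g]) @ axis)

    # ---- integrate theta(t) ----
    thetas, theta_dots, taus, phases, lifts = [], [], [], [], []

    def accel(theta, theta_dot, tau_app, damping):
        return (tau_app + tau_gravity(theta) - damping * theta_dot) / I_pend

    def rk4_step(theta, theta_dot, tau_app, damping):
        f = lambda th, thd: (thd, accel(th, thd, tau_app, damping))
        k1 = f(theta, theta_dot)
        k2 = f(theta + 0.5 * dt * k1[0], theta_dot + 0.5 * dt * k1[1])
        k3 = f(theta + 0.5 * dt * k2[0], theta_dot + 0.5 * dt * k2[1])
        k4 = f(theta + dt * k3[0], theta_dot + dt * k3[1])
        th = theta + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        thd = theta_dot + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        return th, thd

    if cfg.torque_program is not None:
        if cfg.duration is None:
            raise ValueError("duration is required with an explicit torque_program")
        n = int(round(cfg.duration * cfg.frame_rate)) + 1
        theta, theta_dot = cfg.initial_theta, cfg.initial_theta_dot
        for i in range(n):
            t = i * dt
            tau = 0.0
            for t0, t1, tv in cfg.torque_program:
                if t0 <= t < t1:
                    tau = tv
                    break
            thetas.append(theta)
            theta_dots.append(theta_dot)
            taus.append(tau)
            phases.append("programmed")
            lifts.append(lift)
            if abs(theta_dot) > _OMEGA_LIMIT:
                raise InstabilityError(
                    f"|omega| exceeded {_OMEGA_LIMIT} rad/s at t={t:.4f}s"
                )
            theta, theta_dot = rk4_step(theta, theta_dot, tau, 0.0)
    else:
        theta, theta_dot = 0.0, 0.0
        n_fail = cfg.n_attempts - (0 if cfg.mode == "failed" else 1)
        targets = [0.40 * theta_apex] * n_fail
        # failed attempts push just above the quasistatic limit so the
        # body creeps up and falls back instead of being flung over
        grid = np.linspace(0.0, theta_apex, 64)
        tau_grav_peak = max(max(-tau_gravity(th) for th in grid), 0.0)
        tau_fail = 1.05 * tau_grav_peak if tau_grav_peak > 0 else 0.5 * cfg.torque
        push_tau = [tau_fail] * n_fail
        if cfg.mode != "failed":
            targets.append(theta_apex + 0.25)
            push_tau.append(cfg.torque)
        attempt_idx = 0
        phase = "overturned"
        timer = 0.10  # s of initial quiescence
        lift_now = 0.0
        t = 0.0
        max_t = 30.0
        while t < max_t:
            if phase == "overturned":
                tau = 0.0
                timer -= dt
                if timer <= 0 and attempt_idx < len(targets):
                    phase = (
                        "lifting"
                        if (cfg.mode == "lifted_rotating" and lift > 0)
                        else "push"
                    )
                    timer = 0.10
                elif timer <= 0:
                    break
            if phase == "lifting":
                tau = 0.0
                lift_now = min(lift, lift_now + lift * dt / 0.1)
                if lift_now >= lift:
                    phase = "push"
            if phase == "push":
                tau = push_tau[attempt_idx]
                if theta >= targets[attempt_idx]:
                    phase = "coast"
                    tau = 0.0
            if phase == "coast":
                tau = 0.0
                past_apex = attempt_idx == len(targets) - 1 and cfg.mode != "failed"
                if past_apex and theta >= cfg.theta_final:
                    theta, theta_dot = cfg.theta_final, 0.0
                    phase = "righted"
                    timer = 0.25
                elif not past_apex and theta <= 0.0:
                    theta, theta_dot = 0.0, 0.0
                    attempt_idx += 1
                    phase = "overturned"
                    timer = 0.08
                    lift_now = 0.0  # a failed attempt drops the body back
            if phase == "righted":
                tau = 0.0
                timer -= dt
                if timer <= 0:
                    thetas.append(theta)
                    theta_dots.append(0.0)
                    taus.append(0.0)
                    phases.append(phase)
                    lifts.append(lift_now)
                    break
            thetas.append(theta)
            theta_dots.append(theta_dot)
            taus.append(tau)
            phases.append(phase)
            lifts.append(lift_now)
            if abs(theta_dot) > _OMEGA_LIMIT:
                raise InstabilityError("torque program destabilized the pendulum")
            if phase not in ("overturned", "lifting", "righted"):
                damping = cfg.damping if phase == "coast" else 0.0
                theta, theta_dot = rk4_step(theta, theta_dot, tau, damping)
                theta = min(theta, cfg.theta_final)
                if phase == "push" and theta < 0.0:
                    theta, theta_dot = 0.0, 0.0  # ground blocks back-fall
            t += dt

    thetas = np.asarray(thetas)
    theta_dots = np.asarray(theta_dots)
    taus = np.asarray(taus)
    lifts = np.asarray(lifts)
    phases = np.asarray(phases, dtype=object)
    n = thetas.size
    times = np.arange(n) * dt

    # ---- kinematic reconstruction of all landmarks ----
    shift0 = np.array([0.0, 0.0, h0])
    rots = Rotation.from_rotvec(np.outer(thetas, axis))
    quats_xyzw = (rots * R0).as_quat()
    quats = np.column_stack([quats_xyzw[:, 3], quats_xyzw[:, :3]])
    flip = quats[:, 0] < 0
    quats[flip] *= -1

    # the body first translates up by lift (lifted_rotating only), then
    # rotates rigidly about the fixed axis through the (lifted) pivot
    def rigid_motion(p0: np.ndarray) -> np.ndarray:
        """Trajectory of a body-fixed point given at theta=0, lift=0."""
        pre = p0 + np.column_stack([np.zeros((n, 2)), lifts])
        if lift <= 0:
            return pivot + rots.apply(p0 - pivot)
        rotated = pivot + rots.apply(p0 + np.array([0.0, 0.0, lift]) - pivot)
        return np.where((thetas > 0)[:, None], rotated, pre)

    landmarks: dict[str, np.ndarray] = {}
    body_names = list(lm_body)
    for name in body_names:
        landmarks[name] = rigid_motion(R0.apply(lm_body[name]) + shift0)

    righted_feet = {
        "L1": (3.5e-3, 2.5e-3), "R1": (3.5e-3, -2.5e-3),
        "L2": (0.0, 3.0e-3), "R2": (0.0, -3.0e-3),
        "L3": (-3.5e-3, 2.5e-3), "R3": (-3.5e-3, -2.5e-3),
    }
    is_righted = phases == "righted"
    leg_t0 = _leg_positions_t0(cfg, R0, h0, lm_body, stance, lift)
    for leg in LEG_NAMES:
        coxa = landmarks[f"coxa_{leg}"]
        if cfg.rigid_legs:
            landmarks[f"tarsus_{leg}"] = rigid_motion(leg_t0[f"tarsus_{leg}"])
            landmarks[f"femur_tibia_{leg}"] = rigid_motion(
                leg_t0[f"femur_tibia_{leg}"]
            )
            continue
        if leg in stance:
            tarsus = np.tile(stance[leg], (n, 1))
        else:
            # body-frame swing about a ventral rest point so raised feet
            # clear the ground while the body is supine
            z = _swing_z(cfg, leg, times) - 1.5e-3
            off_body = np.column_stack(
                [np.zeros(n), np.full(n, np.sign(lm_body[f"coxa_{leg}"][1]) * 1.5e-3), z]
            )
            tarsus = coxa + (rots * R0).apply(off_body)
        if is_righted.any():
            centre = 0.5 * (
                landmarks["cranial"][is_righted][-1]
                + landmarks["caudal"][is_righted][-1]
            )
            fx, fy = righted_feet[leg]
            planted = np.array([centre[0] + fx, centre[1] + fy, 0.0])
            tarsus = np.where(is_righted[:, None], planted, tarsus)
        joint = 0.5 * (coxa + tarsus) + np.array([0.0, 0.0, 0.5e-3])
        landmarks[f"tarsus_{leg}"] = tarsus
        landmarks[f"femur_tibia_{leg}"] = joint

    landmarks_clean = {k: v.copy() for k, v in landmarks.items()}

    # ---- ground truth: the frozen-leg COM follows the same rigid motion
    com_t = pivot + rots.apply(com0 - pivot)
    PE = M * cfg.gravity * com_t[:, 2]
    KE = 0.5 * I_pend * theta_dots**2
    Z_dv = (rots * R0).apply(np.array([0.0, 0.0, -1.0]))[:, 2]

    truth = GroundTruth(
        times=times,
        theta=thetas,
        theta_dot=theta_dots,
        omega_orbital=np.abs(theta_dots),
        Z_dv=Z_dv,
        quaternions=quats,
        com=com_t,
        PE=PE,
        KE=KE,
        tau_applied=taus,
        phase=phases,
        I_pendulum=I_pend,
        I_spin_com=asm.I_spin,
        leg_fraction=asm.leg_fraction,
        pivot=pivot,
        axis=axis,
        mode=cfg.mode,
        n_attempts=cfg.n_attempts,
        landmarks_clean=landmarks_clean,
        theta_apex=theta_apex,
    )

    noisy = {
        k: v + rng.normal(0.0, cfg.noise_sd, v.shape) if cfg.noise_sd > 0 else v.copy()
        for k, v in landmarks.items()
    }
    trial = TrackedTrial(
        frame_rate=cfg.frame_rate,
        times=times,
        landmarks=noisy,
        substrate="synthetic",
        instar="synthetic",
        body_length=float(np.linalg.norm(lm_body["cranial"] - lm_body["caudal"])),
        mass=cfg.total_mass,
        meta={"mode": cfg.mode, "seed": cfg.seed},
    )
    return trial, truth


def make_reference_pose_library(
    semi_axes=SEMI_AXES_DEFAULT,
    morph: LegMorphometrics | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Canonical single-frame landmark sets for the standard morphology.

    Poses: ``overturned`` (supine, legs raised), ``planted`` (supine,
    feet on the ground — the reference splayed pose for anchor-inertia
    composition), ``lifted`` (body airborne on three stance legs),
    ``apex`` (COM above the pivot) and ``righted`` (upright, all feet
    planted).
    """
    a, b, c = semi_axes
    lm_body = body_landmarks_body_frame(semi_axes)
    R0 = Rotation.from_euler("x", np.pi)
    mm = 1e-3

    def body_at(rot, height):
        return {
            name: rot.apply(p) + np.array([0.0, 0.0, height])
            for name, p in lm_body.items()
        }

    def with_legs(body, feet):
        out = dict(body)
        for leg in LEG_NAMES:
            coxa = out[f"coxa_{leg}"]
            tarsus = np.asarray(feet[leg], float)
            out[f"tarsus_{leg}"] = tarsus
            out[f"femur_tibia_{leg}"] = 0.5 * (coxa + tarsus) + np.array(
                [0.0, 0.0, 0.8e-3]
            )
        return out

    raised = {
        leg: body_landmarks_body_frame(semi_axes)[f"coxa_{leg}"] for leg in LEG_NAMES
    }
    overturned_feet = {
        leg: R0.apply(p + np.array([0.0, np.sign(p[1]) * 1.5e-3, 2.0e-3]))
        + np.array([0, 0, c])
        for leg, p in raised.items()
    }
    # fully-extended splay (feet ~7.5 mm from the midline, at the reach
    # of the outstretched two-segment legs)
    planted_feet = {
        "L1": (5.5 * mm, 5.1 * mm, 0.0), "R1": (5.5 * mm, -5.1 * mm, 0.0),
        "L2": (0.3 * mm, 5.9 * mm, 0.0), "R2": (0.3 * mm, -5.9 * mm, 0.0),
        "L3": (-5.5 * mm, 5.1 * mm, 0.0), "R3": (-5.5 * mm, -5.1 * mm, 0.0),
    }
    lifted_feet = {
        "R1": (3.0 * mm, -2.5 * mm, 0.0), "R2": (0.0, -3.0 * mm, 0.0),
        "R3": (-3.0 * mm, -2.5 * mm, 0.0),
        "L1": (3.0 * mm, 2.0 * mm, 2.5 * mm), "L2": (0.0, 2.5 * mm, 3.0 * mm),
        "L3": (-3.0 * mm, 2.0 * mm, 2.5 * mm),
    }
    R_apex = Rotation.from_rotvec(
        np.array([-1.0, -1.0, 0.0]) / np.sqrt(2) * (np.pi / 2)
    ) * R0
    library = {
        "overturned": with_legs(body_at(R0, c), overturned_feet),
        "planted": with_legs(body_at(R0, c), planted_feet),
        "lifted": with_legs(body_at(R0, c + 2.5 * mm), lifted_feet),
        "apex": with_legs(
            body_at(R_apex, 0.8 * (semi_axes[0] + semi_axes[2])), planted_feet
        ),
        "righted": with_legs(
            body_at(Rotation.identity(), c + 1.5 * mm), planted_feet
        ),
    }
    return library
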