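"""Inverted physical pendulum template for righting rotations.

The template treats the insect as a rigid body rotating about a fixed
pivot point on the ground.  From the COM trajectory and the anchor's
spin inertia it derives orbital angular velocity omega_orbital =
v_orbital / d, the pendulum moment of inertia I_pendulum = I_spin(COM) +
M d^2, the available kinetic energy KE_avail = 1/2 I_pendulum
omega_orbital^2, the natural period, and — from Newton's rotational law
tau_net = I_pendulum alpha_orbital — the net ground reaction torque and
mean force per supporting leg.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .kinematics import GroundPlane
from .smoothing import derivative

__all__ = [
    "G",
    "locate_pivot",
    "orbital_kinematics",
    "pendulum_inertia_and_KE",
    "pendulum_period",
    "rotation_time",
    "reaction_torque_and_force",
    "PivotEstimate",
]

G = 9.81  # m s^-2

D_MIN_DEFAULT = 1e-3  # m; COM-pivot distance guard against omega blow-up


@dataclasses.dataclass(frozen=True)
class PivotEstimate:
    point: np.ndarray  # m, spatial frame
    landmark: str
    stationarity: float  # RMS displacement about the mean, m


def locate_pivot(
    landmarks: dict[str, np.ndarray],
    contact_mask: dict[str, np.ndarray],
    window: slice | None = None,
) -> PivotEstimate:
    """Estimate the fixed ground pivot of a righting attempt.

    The pivot is the time-mean position of the most stationary landmark
    that is in ground contact during the window, preferring body
    (non-tarsus) landmarks over feet; its RMS displacement about the
    mean is reported as a stationarity score.

    Raises
    ------
    ValueError
        If no landmark is in contact anywhere in the window.
    """
    if window is None:
        window = slice(None)
    best: PivotEstimate | None = None
    best_key: tuple[int, float] | None = None
    for name, pos in landmarks.items():
        mask = contact_mask.get(name)
        if mask is None:
            continue
        m = np.asarray(mask[window], bool)
        p = np.asarray(pos[window], float)
        ok = m & np.all(np.isfinite(p), axis=1)
        if ok.sum() < 1:
            continue
        pts = p[ok]
        mean = pts.mean(axis=0)
        rms = float(np.sqrt(np.mean(np.sum((pts - mean) ** 2, axis=1))))
        # prefer true body landmarks over leg joints over feet
        if name.startswith(("tarsus", "femur_tibia", "coxa")):
            rank = 2 if name.startswith("tarsus") else 1
        else:
            rank = 0
        key = (rank, rms)
        if best_key is None or key < best_key:
            best_key = key
            best = PivotEstimate(point=mean, landmark=name, stationarity=rms)
    if best is None:
        raise ValueError("no landmark in ground contact in the window")
    return best


def orbital_kinematics(
    com: np.ndarray,
    pivot: np.ndarray,
    frame_rate: float,
    window_ms: float = 25.0,
    d_min: float = D_MIN_DEFAULT,
    times: np.ndarray | None = None,
):
    """Orbital speed, angular velocity and angular acceleration of the COM.

    v_orbital is the COM speed |dCOM/dt| (local quadratic-regression
    derivative); omega_orbital = v_orbital / d with d the COM-pivot
    distance; alpha_orbital differentiates omega_orbital the same way.
    Frames with d <= d_min are flagged NaN rather than clipped.

    Returns
    -------
    dict with keys d, v_orbital, omega_orbital, alpha_orbital (arrays).
    """
    com = np.asarray(com, float)
    pivot = np.asarray(pivot, float)
    d = np.linalg.norm(com - pivot, axis=1)
    v_vec = derivative(com, frame_rate, window_ms=window_ms, times=times)
    v = np.linalg.norm(v_vec, axis=1)
    omega = np.where(d > d_min, v / np.where(d > d_min, d, np.nan), np.nan)
    alpha = derivative(omega, frame_rate, window_ms=window_ms, times=times)
    return {
        "d": d,
        "v_orbital": v,
        "omega_orbital": omega,
        "alpha_orbital": alpha,
    }


def pendulum_inertia_and_KE(
    I_spin_com, M: float, d, omega_orbital
) -> tuple[np.ndarray, np.ndarray]:
    """I_pendulum = I_spin(COM axis) + M d^2 and KE_avail = 1/2 I w^2."""
    I_spin_com = np.asarray(I_spin_com, float)
    d = np.asarray(d, float)
    omega = np.asarray(omega_orbital, float)
    I_pend = I_spin_com + M * d * d
    return I_pend, 0.5 * I_pend * omega**2


def pendulum_period(I_pendulum: float, M: float, d: float) -> float:
    """Natural period T = 2 pi sqrt(I_pendulum / (M g d))."""
    if not (I_pendulum > 0 and M > 0 and d > 0):
        raise ValueError("I_pendulum, M and d must all be positive")
    return float(2.0 * np.pi * np.sqrt(I_pendulum / (M * G * d)))


def rotation_time(theta: float, I_rot: float, tau: float) -> float:
    """Time to rotate through angle theta under constant torque tau:
    theta = 1/2 (tau / I) t^2  =>  t = sqrt(2 theta I / tau)."""
    if not (theta > 0 and I_rot > 0 and tau > 0):
        raise ValueError("theta, I_rot and tau must all be positive")
    return float(np.sqrt(2.0 * theta * I_rot / tau))


def reaction_torque_and_force(
    I_pendulum,
    alpha_orbital,
    M: float,
    r_com,
    r_perp,
    n_tarsi,
    d=None,
    gravity_arm: str = "r_com",
):
    """Net torque, gravity torque, ground reaction torque and force per leg.

    tau_net = I_pendulum alpha_orbital; tau_grav = -M g r_arm with
    r_arm the horizontal pivot->COM-projection distance (``r_com``, the
    physically correct arm for a vertical force) or the full COM-pivot
    distance ``d`` when ``gravity_arm='d'``;
    tau_reaction = tau_net - tau_grav = r_perp F_reaction; F_leg =
    F_reaction / n_tarsi, also reported in body weights.

    Frames with n_tarsi = 0 or r_perp = 0 yield NaN force entries.
    """
    if gravity_arm not in ("r_com", "d"):
        raise ValueError("gravity_arm must be 'r_com' or 'd'")
    I_pendulum = np.asarray(I_pendulum, float)
    alpha = np.asarray(alpha_orbital, float)
    r_com = np.asarray(r_com, float)
    r_perp = np.asarray(r_perp, float)
    n_tarsi = np.asarray(n_tarsi, float)
    if gravity_arm == "d":
        if d is None:
            raise ValueError("gravity_arm='d' requires the d series")
        arm = np.asarray(d, float)
    else:
        arm = r_com
    tau_net = I_pendulum * alpha
    tau_grav = -M * G * arm
    tau_reaction = tau_net - tau_grav
    with np.errstate(divide="ignore", invalid="ignore"):
        F_reaction = np.where(r_perp > 0, tau_reaction / r_perp, np.nan)
        F_leg = np.where(n_tarsi >= 1, F_reaction / n_tarsi, np.nan)
    return {
        "tau_net": tau_net,
        "tau_grav": tau_grav,
        "tau_reaction": tau_reaction,
        "F_reaction": F_reaction,
        "F_leg": F_leg,
        "F_leg_bw": F_leg / (M * G),
    }


def mean_tarsus_moment_arm(
    tarsi: dict[str, np.ndarray],
    contact: dict[str, np.ndarray],
    pivot: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean 3D tarsus-pivot distance over in-contact tarsi.

    Returns (r_perp, n_tarsi); frames with no tarsus in contact give
    r_perp = NaN and n_tarsi = 0.
    """
    names = sorted(tarsi)
    n = next(iter(tarsi.values())).shape[0]
    dist = np.full((n, len(names)), np.nan)
    mask = np.zeros((n, len(names)), bool)
    for j, name in enumerate(names):
        p = np.asarray(tarsi[name], float)
        c = np.asarray(contact[name], bool)
        ok = c & np.all(np.isfinite(p), axis=1)
        dist[ok, j] = np.linalg.norm(p[ok] - pivot, axis=1)
        mask[:, j] = ok
    n_tarsi = mask.sum(axis=1)
    totals = np.nansum(np.where(mask, dist, 0.0), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perp = np.where(n_tarsi > 0, totals / n_tarsi, np.nan)
    return r_perp, n_tarsi
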