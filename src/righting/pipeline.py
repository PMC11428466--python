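"""End-to-end analysis of one righting trial.

Orchestrates the full chain: standardized scaling, smoothing, ground
plane, attitude/angular kinematics, anchor mass composition, the
inverted-pendulum template, energetics, stability margins, leg
coordination and behavioural segmentation.  The result bundles
per-frame metric tables (ready for ``io.write_metrics``) with scalar
trial summaries.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial.transform import Rotation

from . import body_model, coordination, energetics, ethogram, pendulum, stability
from .io import LEG_NAMES, LegMorphometrics, TrackedTrial, default_morphometrics
from .kinematics import GroundPlane, KinematicSeries, compute_kinematics, fit_ground_plane
from .smoothing import derivative
from .synthetic import SEMI_AXES_DEFAULT, body_mesh_anatomical

__all__ = ["AnalysisConfig", "TrialAnalysis", "analyze_trial"]


@dataclasses.dataclass
class AnalysisConfig:
    body_window_ms: float = 25.0
    leg_window_ms: float = 5.0
    robust_smoothing: bool = True
    contact_tolerance: float | None = None  # m; default 2x plane residual SD
    contact_tolerance_floor: float = 0.5e-3  # m
    gravity_arm: str = "r_com"  # 'r_com' (text definition) or 'd'
    d_min: float = 1e-3  # m
    standardize: bool = True
    rn_eps: float = 1e-10  # J


@dataclasses.dataclass
class TrialAnalysis:
    trial: TrackedTrial
    kin: KinematicSeries
    plane: GroundPlane
    metrics: pd.DataFrame  # per-frame table of all series
    events: energetics.OverturningEvents
    segmentation: ethogram.AttemptSegmentation
    method: str
    pivot: pendulum.PivotEstimate | None
    coordination: dict
    summary: dict


def _ground_plane_from_feet(trial: TrackedTrial) -> GroundPlane:
    """Fit the ground plane to the cloud of low foot points.

    Tarsus samples in the lowest 15% of the trial's foot-height range
    stand in for the visually-identified in-contact points.
    """
    pts = []
    for leg in LEG_NAMES:
        p = trial.landmarks.get(f"tarsus_{leg}")
        if p is not None:
            pts.append(p[np.all(np.isfinite(p), axis=1)])
    allp = np.concatenate(pts, axis=0)
    z = allp[:, 2]
    cut = np.quantile(z, 0.15)
    low = allp[z <= cut]
    return fit_ground_plane(low)


def analyze_trial(
    trial: TrackedTrial,
    mesh: trimesh.Trimesh | None = None,
    morph: LegMorphometrics | None = None,
    config: AnalysisConfig | None = None,
    plane: GroundPlane | None = None,
) -> TrialAnalysis:
    """Run the full biomechanical analysis on a tracked trial."""
    cfg = config or AnalysisConfig()
    if morph is None:
        morph = default_morphometrics()
    if cfg.standardize and trial.body_length is not None:
        trial, _ = body_model.scale_to_standard(trial)
    if mesh is None:
        # synthetic stand-in, already in the anatomical frame (origin at
        # the cranial-caudal landmark midpoint, x cranial, z dorsal)
        mesh = body_mesh_anatomical(SEMI_AXES_DEFAULT)
    M_total = trial.mass if trial.mass else body_model.MASS_STANDARD
    body_mass = M_total - morph.total_leg_mass
    if body_mass <= 0:
        raise ValueError("leg masses exceed the trial's total mass")
    body_props = body_model.mesh_mass_properties(mesh, body_mass)

    kin = compute_kinematics(
        trial,
        body_window_ms=cfg.body_window_ms,
        leg_window_ms=cfg.leg_window_ms,
        robust=cfg.robust_smoothing,
    )
    if plane is None:
        plane = _ground_plane_from_feet(
            TrackedTrial(
                frame_rate=trial.frame_rate,
                times=trial.times,
                landmarks=kin.landmarks_smooth,
            )
        )
    tol = cfg.contact_tolerance
    if tol is None:
        tol = max(2.0 * plane.residual_sd, cfg.contact_tolerance_floor)
    contacts = stability.detect_contacts(kin.landmarks_smooth, plane, tol)

    n = trial.n_frames
    fps = trial.frame_rate

    # --- anchor composition per frame ---
    com_whole = np.full((n, 3), np.nan)
    com_body = np.full((n, 3), np.nan)
    I_spin = np.full(n, np.nan)
    leg_frac = np.full(n, np.nan)
    omega_hat_mean = _dominant_axis(kin.omega)
    for i in range(n):
        att = kin.attitude(i)
        if att is None:
            continue
        w = kin.omega[i]
        nw = np.linalg.norm(w)
        axis = w / nw if np.isfinite(nw) and nw > 1e-6 else omega_hat_mean
        body_com = att.apply(body_props.com)
        leg_lm = {
            name: kin.landmarks_smooth[name][i]
            for name in kin.landmarks_smooth
            if name.split("_")[0] in ("coxa", "tarsus") or name.startswith("femur_tibia")
        }
        asm = body_model.assemble_anchor(
            body_props, att.rotation, body_com, leg_lm, morph, axis
        )
        com_whole[i] = asm.com
        com_body[i] = body_com
        I_spin[i] = asm.I_spin
        leg_frac[i] = asm.leg_fraction

    v_com = derivative(com_whole, fps, window_ms=cfg.body_window_ms, times=trial.times)
    com_speed = np.linalg.norm(v_com, axis=1)

    # --- energetics (needed for the pivot window) ---
    Z_com = plane.signed_distance(com_whole)
    Z_body = plane.signed_distance(com_body)
    PE_total = energetics.potential_energy(Z_com, M_total)
    PE_body = energetics.potential_energy(Z_body, body_mass)
    PE_legs = PE_total - PE_body
    events = energetics.detect_apex_and_overturning(
        trial.times, PE_total, kin.Z_dv, fps
    )

    # --- pivot + template (pivot held fixed, estimated on the
    #     active-overturning window so resting frames don't dominate) ---
    if events.overturning_interval is not None:
        lo_t, hi_t = events.overturning_interval
        idx = np.flatnonzero((trial.times >= lo_t) & (trial.times <= hi_t))
        pivot_window = slice(int(idx[0]), int(idx[-1]) + 1) if idx.size else None
    else:
        pivot_window = None
    try:
        piv = pendulum.locate_pivot(
            kin.landmarks_smooth, contacts, window=pivot_window
        )
        pivot_pt = piv.point
    except ValueError:
        try:
            piv = pendulum.locate_pivot(kin.landmarks_smooth, contacts)
            pivot_pt = piv.point
        except ValueError:
            piv, pivot_pt = None, None

    if pivot_pt is not None:
        orb = pendulum.orbital_kinematics(
            com_whole, pivot_pt, fps, window_ms=cfg.body_window_ms,
            d_min=cfg.d_min, times=trial.times,
        )
        I_pend, KE_avail = pendulum.pendulum_inertia_and_KE(
            I_spin, M_total, orb["d"], orb["omega_orbital"]
        )
        tarsi = {f"tarsus_{leg}": kin.landmarks_smooth[f"tarsus_{leg}"]
                 for leg in LEG_NAMES if f"tarsus_{leg}" in kin.landmarks_smooth}
        tarsi_contact = {k: contacts[k] for k in tarsi}
        r_perp, n_tarsi = pendulum.mean_tarsus_moment_arm(
            tarsi, tarsi_contact, pivot_pt
        )
        com_ground = plane.to_plane_coords(com_whole)
        pivot_ground = plane.to_plane_coords(pivot_pt[None, :])[0]
        r_com = np.linalg.norm(com_ground - pivot_ground, axis=1)
        forces = pendulum.reaction_torque_and_force(
            I_pend, orb["alpha_orbital"], M_total, r_com, r_perp, n_tarsi,
            d=orb["d"], gravity_arm=cfg.gravity_arm,
        )
    else:
        nanarr = np.full(n, np.nan)
        orb = {k: nanarr for k in ("d", "v_orbital", "omega_orbital", "alpha_orbital")}
        I_pend, KE_avail = np.full(n, np.nan), np.full(n, np.nan)
        r_perp, n_tarsi = np.full(n, np.nan), np.zeros(n)
        r_com = np.full(n, np.nan)
        forces = {k: np.full(n, np.nan) for k in
                  ("tau_net", "tau_grav", "tau_reaction", "F_reaction",
                   "F_leg", "F_leg_bw")}

    # --- righting number ---
    apex_idx = int(np.nanargmax(PE_total))
    PE_max = float(PE_total[apex_idx])
    dPE = np.maximum(PE_max - PE_total, 0.0)
    RN, rn_sat = energetics.righting_number(KE_avail, dPE, eps=cfg.rn_eps)

    # --- stability ---
    SM = np.full(n, np.nan)
    ISM = np.full(n, np.nan)
    SM_ratio = np.full(n, np.nan)
    leg_contact_names = {f"tarsus_{leg}" for leg in LEG_NAMES}
    for i in range(n):
        pts = [
            kin.landmarks_smooth[name][i]
            for name, mask in contacts.items()
            if mask[i]
        ]
        if not pts or not np.all(np.isfinite(com_whole[i])):
            continue
        pts2 = plane.to_plane_coords(np.asarray(pts))
        com2 = plane.to_plane_coords(com_whole[i][None, :])[0]
        res = stability.stability_margin(pts2, com2)
        SM[i], ISM[i], SM_ratio[i] = res.SM, res.ISM, res.SM_ratio

    # --- coordination (first analyzed frame to apex) ---
    attitudes = [kin.attitude(i) for i in range(n)]
    z_tarsus = {}
    for leg in LEG_NAMES:
        key = f"tarsus_{leg}"
        if key in kin.landmarks_smooth:
            z_tarsus[leg] = coordination.tarsus_body_z(
                kin.landmarks_smooth[key], attitudes
            )
    stop = max(apex_idx, 16)
    try:
        coord = coordination.coordination_summary(
            {k: v[:stop] for k, v in z_tarsus.items()}, fps
        )
    except ValueError:
        coord = {"pairs": [], "auto": {}}

    # --- ethogram ---
    dorsum_contact = contacts.get("dorsum_mid", np.zeros(n, bool))
    tarsi_count = np.sum(
        [contacts[name] for name in sorted(leg_contact_names & set(contacts))],
        axis=0,
    )
    seg = ethogram.segment_attempts(
        trial.times, kin.Z_dv, dorsum_contact, tarsi_count, com_speed
    )
    body_contact_any = np.any(
        [m for name, m in contacts.items() if name not in leg_contact_names
         and not name.startswith(("femur_tibia", "coxa"))],
        axis=0,
    )
    if events.overturning_interval is not None:
        lo, hi = events.overturning_interval
        sel = (trial.times >= lo) & (trial.times <= hi)
    else:
        sel = np.zeros(n, bool)
    rot_axis = _dominant_axis(kin.omega[sel]) if sel.any() else np.full(3, np.nan)
    pitch_axes = np.full((n, 3), np.nan)
    for i, att in enumerate(attitudes):
        if att is not None:
            pitch_axes[i] = att.rotation.as_matrix()[:, 1]
    lat = (
        np.nanmean(pitch_axes[sel], axis=0)
        if sel.any()
        else np.nanmean(pitch_axes, axis=0)
    )
    method = ethogram.classify_method(
        body_contact_any[sel] if sel.any() else body_contact_any,
        rot_axis,
        lat,
        piv.landmark if piv is not None else None,
    )

    metrics = pd.DataFrame(
        {
            "time_s": trial.times,
            "Z_dv": kin.Z_dv,
            "yaw_rad": kin.euler[:, 0],
            "pitch_rad": kin.euler[:, 1],
            "roll_rad": kin.euler[:, 2],
            "omega_x": kin.omega[:, 0],
            "omega_y": kin.omega[:, 1],
            "omega_z": kin.omega[:, 2],
            "omega_spin_rp": kin.omega_spin_rp,
            "com_x_m": com_whole[:, 0],
            "com_y_m": com_whole[:, 1],
            "com_z_m": com_whole[:, 2],
            "com_speed_m_s": com_speed,
            "d_m": orb["d"],
            "v_orbital_m_s": orb["v_orbital"],
            "omega_orbital_rad_s": orb["omega_orbital"],
            "alpha_orbital_rad_s2": orb["alpha_orbital"],
            "I_spin_kg_m2": I_spin,
            "leg_inertia_fraction": leg_frac,
            "I_pendulum_kg_m2": I_pend,
            "KE_avail_J": KE_avail,
            "PE_total_J": PE_total,
            "PE_body_J": PE_body,
            "PE_legs_J": PE_legs,
            "dPE_J": dPE,
            "RN": RN,
            "RN_saturated": rn_sat.astype(float),
            "tau_net_Nm": forces["tau_net"],
            "tau_grav_Nm": forces["tau_grav"],
            "tau_reaction_Nm": forces["tau_reaction"],
            "F_reaction_N": forces["F_reaction"],
            "F_leg_N": forces["F_leg"],
            "F_leg_bw": forces["F_leg_bw"],
            "r_com_m": r_com,
            "r_perp_m": r_perp,
            "n_tarsi_contact": n_tarsi,
            "SM_m": SM,
            "ISM_m": ISM,
            "SM_ratio_pct": SM_ratio,
        }
    )
    summary = {
        "method": method,
        "success": seg.success,
        "attempts": seg.attempts,
        "time_to_right_s": seg.time_to_right,
        "time_per_attempt_s": seg.time_per_attempt,
        "apex_time_s": events.apex_time,
        "flipping_time_s": events.flipping_time,
        "PE_gain_J": PE_max - float(PE_total[np.isfinite(PE_total)][0])
        if np.isfinite(PE_total).any()
        else np.nan,
        "mean_leg_inertia_fraction": float(np.nanmean(leg_frac)),
        "pivot_landmark": piv.landmark if piv is not None else None,
        "contact_tolerance_m": tol,
    }
    return TrialAnalysis(
        trial=trial,
        kin=kin,
        plane=plane,
        metrics=metrics,
        events=events,
        segmentation=seg,
        method=method,
        pivot=piv,
        coordination=coord,
        summary=summary,
    )


def _dominant_axis(omega: np.ndarray) -> np.ndarray:
    """Principal direction of an angular-velocity series (unit vector)."""
    w = np.asarray(omega, float)
    w = w[np.all(np.isfinite(w), axis=1)]
    if w.shape[0] == 0:
        return np.full(3, np.nan)
    # align signs to the strongest sample before averaging
    ref = w[np.argmax(np.linalg.norm(w, axis=1))]
    signs = np.sign(w @ ref)
    signs[signs == 0] = 1.0
    mean = (w * signs[:, None]).mean(axis=0)
    nrm = np.linalg.norm(mean)
    return mean / nrm if nrm > 0 else np.full(3, np.nan)
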