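"""Potential energy, righting number, and the pitch-roll PE landscape.

PE = M g Z with Z the COM height over the fitted ground plane.  The
increase still required to surmount the barrier at time t is
dPE(t) = PE_max - PE(t); the dimensionless righting number
RN(t) = KE_avail(t) / dPE(t) measures the contribution of inertial
reorientation: RN >= 1 permits purely dynamic righting, RN << 1 is
quasistatic.  The simplified landscape evaluates PE of the body mesh
alone over all pitch-roll attitudes with its lowest point touching the
ground.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .pendulum import G
from .smoothing import derivative

__all__ = [
    "potential_energy",
    "righting_number",
    "detect_apex_and_overturning",
    "pe_landscape",
    "PELandscape",
    "OverturningEvents",
]

RN_EPS_DEFAULT = 1e-10  # J; dPE below this flags RN as saturated


def potential_energy(Z, M: float):
    """PE = M g Z (J) for COM height Z (m) above the ground plane."""
    if M <= 0:
        raise ValueError("mass must be positive")
    return M * G * np.asarray(Z, float)


def righting_number(KE_avail, dPE, eps: float = RN_EPS_DEFAULT):
    """RN = KE_avail / dPE, with dPE < eps flagged NaN (saturated).

    Returns (RN, saturated_mask).
    """
    KE = np.asarray(KE_avail, float)
    dPE = np.asarray(dPE, float)
    if np.any(dPE[np.isfinite(dPE)] < 0):
        raise ValueError("dPE must be non-negative")
    if np.any(KE[np.isfinite(KE)] < 0):
        raise ValueError("KE_avail must be non-negative")
    saturated = dPE < eps
    with np.errstate(divide="ignore", invalid="ignore"):
        rn = np.where(saturated, np.nan, KE / dPE)
    return rn, saturated


@dataclasses.dataclass(frozen=True)
class OverturningEvents:
    apex_time: float  # s, argmax of total PE
    flipping_time: float | None  # s, first downward crossing of Z_dv = 0
    overturning_interval: tuple[float, float] | None  # s


def detect_apex_and_overturning(
    times: np.ndarray,
    PE_total: np.ndarray,
    Z_dv: np.ndarray,
    frame_rate: float,
    rate_threshold: float = 0.5,
) -> OverturningEvents:
    """Locate the PE apex, the flipping point, and active overturning.

    Active overturning is the maximal contiguous interval containing the
    flipping time where |dZ_dv/dt| >= ``rate_threshold`` times its trial
    maximum.  If Z_dv never crosses zero downward the attempt failed and
    flipping/overturning are None.
    """
    times = np.asarray(times, float)
    PE = np.asarray(PE_total, float)
    zdv = np.asarray(Z_dv, float)
    apex_idx = int(np.nanargmax(PE))
    apex_time = float(times[apex_idx])

    flip_idx = None
    for i in range(1, times.size):
        if np.isfinite(zdv[i - 1]) and np.isfinite(zdv[i]):
            if zdv[i - 1] > 0 >= zdv[i]:
                flip_idx = i
                break
    if flip_idx is None:
        return OverturningEvents(apex_time, None, None)
    # linear interpolation of the crossing instant
    z0, z1 = zdv[flip_idx - 1], zdv[flip_idx]
    frac = z0 / (z0 - z1)
    flip_time = float(times[flip_idx - 1] + frac * (times[flip_idx] - times[flip_idx - 1]))

    rate = np.abs(derivative(zdv, frame_rate, times=times))
    peak = np.nanmax(rate)
    if not np.isfinite(peak) or peak <= 0:
        return OverturningEvents(apex_time, flip_time, None)
    fast = rate >= rate_threshold * peak
    lo = flip_idx
    while lo - 1 >= 0 and fast[lo - 1]:
        lo -= 1
    hi = flip_idx
    while hi + 1 < times.size and fast[hi + 1]:
        hi += 1
    return OverturningEvents(
        apex_time, flip_time, (float(times[lo]), float(times[hi]))
    )


@dataclasses.dataclass
class PELandscape:
    """PE of the body mesh vs pitch and roll with a ground point contact."""

    pitch: np.ndarray  # rad, grid vector
    roll: np.ndarray  # rad, grid vector
    PE: np.ndarray  # J, shape (len(pitch), len(roll))

    def to_frame(self):
        import pandas as pd

        p, r = np.meshgrid(self.pitch, self.roll, indexing="ij")
        return pd.DataFrame(
            {
                "pitch_rad": p.ravel(),
                "roll_rad": r.ravel(),
                "PE_J": self.PE.ravel(),
            }
        )


def pe_landscape(
    mesh: trimesh.Trimesh,
    M_body: float,
    pitch_grid: np.ndarray,
    roll_grid: np.ndarray,
) -> PELandscape:
    """Simplified pitch-roll PE landscape of the body mesh.

    For each (pitch, roll) with yaw = 0 the mesh is rotated (intrinsic
    Tait-Bryan z-y'-x''), dropped so its lowest vertex touches Z = 0,
    and PE = M_body g Z_COM recorded.  Yaw leaves COM height unchanged
    for a point contact so the landscape is two-dimensional.
    """
    pitch_grid = np.asarray(pitch_grid, float)
    roll_grid = np.asarray(roll_grid, float)
    verts = np.asarray(mesh.vertices, float)
    com = np.asarray(
        mesh.center_mass if mesh.is_watertight else verts.mean(axis=0), float
    )
    PE = np.empty((pitch_grid.size, roll_grid.size))
    for i, th in enumerate(pitch_grid):
        for j, ph in enumerate(roll_grid):
            R = Rotation.from_euler("ZYX", [0.0, th, ph]).as_matrix()
            vz = verts @ R.T[:, 2]  # rotated vertex Z
            z_com = com @ R.T[:, 2]
            PE[i, j] = M_body * G * (z_com - vz.min())
    return PELandscape(pitch=pitch_grid, roll=roll_grid, PE=PE)
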