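"""Behavioral segmentation of righting trials.

An attempt runs from the moment the overturned insect lifts its dorsum
off the ground until it either rights (comes to rest on all feet, dorsum
up) or falls back onto its back; a trial fails if no attempt succeeds
within the 30 s observation limit.  Successful attempts are classified
into one of three stereotypic methods: diagonal rotating (body pivot on
the ground, rotation axis between pitch and roll), lifted rotating (legs
only, body airborne), and pitching (somersault about the caudal end).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "segment_attempts",
    "classify_method",
    "behavior_frequencies",
    "friction_from_tilt",
    "AttemptSegmentation",
]

V_REST_DEFAULT = 5e-3  # m/s; "at rest" COM speed threshold
REST_HOLD_S = 0.100  # s; how long rest must be sustained
ZDV_SUPINE = 0.9  # Z_dv above this counts as on-the-back
TRIAL_LIMIT_S = 30.0
PITCH_AXIS_CONE_DEG = 30.0


@dataclasses.dataclass
class AttemptSegmentation:
    windows: list[tuple[float, float]]  # attempt [start, end] times, s
    success: bool
    time_to_right: float | None  # s, start of first attempt to success
    time_per_attempt: float | None  # s, total attempting time / attempts

    @property
    def attempts(self) -> int:
        return len(self.windows)


def segment_attempts(
    times: np.ndarray,
    Z_dv: np.ndarray,
    dorsum_contact: np.ndarray,
    tarsi_contact_count: np.ndarray,
    com_speed: np.ndarray,
    v_rest: float = V_REST_DEFAULT,
) -> AttemptSegmentation:
    """Segment a trial into righting attempts and score success.

    An attempt starts when the dorsum leaves contact while Z_dv >
    0.9 (supine); it ends in success when Z_dv < 0, all six tarsi are in
    contact and COM speed stays below ``v_rest`` for 100 ms, or in
    failure when the dorsum recontacts the ground with Z_dv > 0.9.
    """
    times = np.asarray(times, float)
    zdv = np.asarray(Z_dv, float)
    dorsum = np.asarray(dorsum_contact, bool)
    n_tarsi = np.asarray(tarsi_contact_count, float)
    speed = np.asarray(com_speed, float)
    n = times.size
    if not (zdv.size == dorsum.size == n_tarsi.size == speed.size == n):
        raise ValueError("all series must share one time base")

    dt = (times[-1] - times[0]) / max(n - 1, 1)
    hold = max(1, int(round(REST_HOLD_S / max(dt, 1e-12))))
    debounce = max(1, int(round(0.010 / max(dt, 1e-12))))  # 10 ms
    windows: list[tuple[float, float]] = []
    success = False
    success_time = None
    i = 0
    in_attempt = False
    start_t = None
    while i < n:
        if times[i] - times[0] > TRIAL_LIMIT_S:
            break
        if not in_attempt:
            if (
                i > 0
                and zdv[i] > ZDV_SUPINE
                and dorsum[i - 1]
                and not np.any(dorsum[i : min(n, i + debounce)])
            ):
                in_attempt = True
                start_t = times[i]
        else:
            # success: righted, all feet down, sustained rest
            if zdv[i] < 0 and n_tarsi[i] >= 6:
                j_end = min(n, i + hold)
                seg = speed[i:j_end]
                if j_end - i >= hold and np.all(seg[np.isfinite(seg)] < v_rest):
                    windows.append((start_t, float(times[i])))
                    success = True
                    success_time = float(times[i])
                    in_attempt = False
                    break
            # failure: fell back onto the dorsum (sustained recontact)
            if (
                zdv[i] > ZDV_SUPINE
                and i - debounce + 1 >= 0
                and np.all(dorsum[max(0, i - debounce + 1) : i + 1])
            ):
                windows.append((start_t, float(times[i])))
                in_attempt = False
        i += 1
    if in_attempt:
        windows.append((start_t, float(times[min(i, n - 1)])))
    attempting = sum(b - a for a, b in windows)
    return AttemptSegmentation(
        windows=windows,
        success=success,
        time_to_right=(
            success_time - windows[0][0] if success and windows else None
        ),
        time_per_attempt=attempting / len(windows) if windows else None,
    )


def classify_method(
    body_contact_any: np.ndarray,
    rotation_axis: np.ndarray,
    pitch_axis: np.ndarray,
    pivot_landmark: str | None,
    axis_cone_deg: float = PITCH_AXIS_CONE_DEG,
) -> str:
    """Classify a righting attempt's method.

    Parameters
    ----------
    body_contact_any : bool array
        Per-frame flag for any body (non-leg) landmark in ground contact
        during active overturning.
    rotation_axis : (3,)
        Dominant rotation axis (spatial frame) during overturning.
    pitch_axis : (3,)
        Body lateral (pitch) axis direction in the spatial frame.
    pivot_landmark : str or None
        Name of the landmark serving as pivot.

    Returns one of ``lifted_rotating``, ``pitching``,
    ``diagonal_rotating`` or ``none``.
    """
    body_contact_any = np.asarray(body_contact_any, bool)
    if body_contact_any.size == 0:
        return "none"
    if not body_contact_any.any():
        return "lifted_rotating"
    axis = np.asarray(rotation_axis, float)
    na = np.linalg.norm(axis)
    if not np.isfinite(na) or na <= 0:
        return "none"
    axis = axis / na
    lat = np.asarray(pitch_axis, float)
    lat = lat / np.linalg.norm(lat)
    ang = np.degrees(np.arccos(np.clip(abs(axis @ lat), -1.0, 1.0)))
    if ang <= axis_cone_deg and pivot_landmark == "caudal":
        return "pitching"
    return "diagonal_rotating"


def behavior_frequencies(counts: dict[str, int]) -> dict[str, float]:
    """Percentage of trials per righting method, to one decimal place."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    return {k: round(100.0 * c / total, 1) for k, c in counts.items()}


def friction_from_tilt(psi: float) -> float:
    """Static friction coefficient mu_s = tan(psi) from the sliding angle.

    ``psi`` is the minimum inclined-plane tilt (rad) at which the
    overturned specimen first slides; psi >= pi/2 signals that it rolled
    instead of sliding (only a lower bound exists) and is rejected.
    """
    if not 0 <= psi < np.pi / 2:
        raise ValueError("psi must lie in [0, pi/2)")
    return float(np.tan(psi))
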