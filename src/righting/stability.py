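"""Support polygon and static stability margins.

The support polygon is the 2D convex hull of all ground-contact points
(leg tarsi plus any body point within contact tolerance), projected onto
the fitted ground plane.  The stability margin SM is the signed shortest
distance from the COM ground-projection to the polygon boundary
(positive strictly inside, negative outside); the ideal stability margin
ISM is that distance when the projection sits at the polygon's area
centroid, so SM:ISM <= 100% measures closeness to optimal static
stability.  Degenerate supports (one or two points) cannot enclose the
COM, so SM is the negated distance to the point/segment and ISM = 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point, Polygon

from .kinematics import GroundPlane

__all__ = [
    "detect_contacts",
    "stability_margin",
    "StabilityResult",
]


def detect_contacts(
    landmarks: dict[str, np.ndarray],
    plane: GroundPlane,
    tolerance: float,
) -> dict[str, np.ndarray]:
    """Per-frame boolean contact mask for each landmark.

    A landmark contacts the ground iff its unsigned distance to the
    fitted plane is within ``tolerance`` (default use: twice the plane's
    residual SD, i.e. 0.5 mm for 0.25 mm tracking).
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be positive")
    out = {}
    for name, pos in landmarks.items():
        pos = np.asarray(pos, float)
        d = plane.signed_distance(pos)
        out[name] = np.where(
            np.all(np.isfinite(pos), axis=1), np.abs(d) <= tolerance, False
        )
    return out


@dataclasses.dataclass
class StabilityResult:
    SM: float  # m, signed
    ISM: float  # m
    SM_ratio: float  # percent, SM/ISM * 100 (NaN for degenerate hulls)
    polygon: np.ndarray  # (k, 2) ordered hull vertices


def stability_margin(points_2d: np.ndarray, com_2d: np.ndarray) -> StabilityResult:
    """Signed stability margin of a contact point set.

    Parameters
    ----------
    points_2d : (n, 2)
        Ground-plane coordinates of in-contact points (n >= 1).
    com_2d : (2,)
        Ground-plane projection of the whole-insect COM.
    """
    pts = np.atleast_2d(np.asarray(points_2d, float))
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    com = Point(np.asarray(com_2d, float))
    if pts.shape[0] == 0:
        raise ValueError("need at least one contact point")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if isinstance(hull, Polygon):
        boundary = hull.exterior
        dist = com.distance(boundary)
        sm = dist if hull.contains(com) else -dist
        centroid = hull.centroid
        ism = centroid.distance(boundary)
        ratio = 100.0 * sm / ism if ism > 0 else np.nan
        verts = np.asarray(boundary.coords)[:-1]
    else:
        # 1-2 distinct points: a point/segment support cannot enclose
        # the COM projection
        if isinstance(hull, (Point, LineString)):
            sm = -com.distance(hull)
        else:  # pragma: no cover
            sm = -com.distance(hull)
        ism = 0.0
        ratio = np.nan
        verts = np.unique(pts, axis=0)
    return StabilityResult(
        SM=float(sm), ISM=float(ism), SM_ratio=float(ratio), polygon=verts
    )
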