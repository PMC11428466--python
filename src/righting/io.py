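"""Reading and writing of on-disk artifacts.

Landmark trajectory tables are flat CSV files with columns
``frame,time_s,<name>_X,<name>_Y,<name>_Z`` — the layout produced by
DLT-based multi-camera reconstruction tools.  Body meshes are STL.  All
internal computation is in SI units (m, kg, s); unit conversion happens
only at this boundary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh
import yaml

__all__ = [
    "CANONICAL_LANDMARKS",
    "MINIMAL_LANDMARKS",
    "LEG_NAMES",
    "TrackedTrial",
    "LegMorphometrics",
    "SchemaError",
    "FormatError",
    "GeometryError",
    "read_landmark_table",
    "write_landmark_table",
    "read_body_mesh",
    "read_morphometrics",
    "default_morphometrics",
    "write_metrics",
    "read_metrics",
]

LEG_NAMES = ("L1", "L2", "L3", "R1", "R2", "R3")

#: Canonical landmark schema: 3 body points + 3 points per leg (proximal
#: coxa, femur-tibia joint, tarsus).  A superset of the 16-18 points a
#: typical trial tracks; individual trials may omit columns not in the
#: minimal schema.
CANONICAL_LANDMARKS = (
    ("cranial", "caudal", "dorsum_mid")
    + tuple(f"coxa_{leg}" for leg in LEG_NAMES)
    + tuple(f"femur_tibia_{leg}" for leg in LEG_NAMES)
    + tuple(f"tarsus_{leg}" for leg in LEG_NAMES)
)

#: Smallest schema the downstream pipeline can run on.
MINIMAL_LANDMARKS = ("cranial", "caudal", "dorsum_mid") + tuple(
    f"tarsus_{leg}" for leg in LEG_NAMES
)

_TIME_TOL = 1e-9  # s; allowed jitter of the uniform time base


class SchemaError(ValueError):
    """A required landmark column is missing from an input table."""


class FormatError(ValueError):
    """An input file violates the format contract (e.g. non-uniform time)."""


class GeometryError(ValueError):
    """Mesh or point-set geometry is unusable (open mesh, collinear points)."""


@dataclasses.dataclass
class TrackedTrial:
    """Time-indexed named-landmark 3D coordinates for one righting trial.

    Coordinates are metres in the laboratory spatial frame with Z vertical
    up; missing samples are NaN.
    """

    frame_rate: float
    times: np.ndarray
    landmarks: dict[str, np.ndarray]  # name -> (n_frames, 3) in m
    substrate: str = ""
    instar: str = ""
    body_length: float | None = None  # head-caudal L_body, m
    mass: float | None = None  # whole-insect mass, kg
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        n = self.times.size
        if n > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise FormatError("times must be strictly increasing")
            if np.ptp(dt) > _TIME_TOL:
                raise FormatError(
                    f"non-uniform time base (spread {np.ptp(dt):.3g} s)"
                )
        for name, xyz in self.landmarks.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (n, 3):
                raise FormatError(
                    f"landmark {name!r} has shape {xyz.shape}, expected ({n}, 3)"
                )
            self.landmarks[name] = xyz

    @property
    def n_frames(self) -> int:
        return self.times.size

    def landmark_array(self, names: Sequence[str]) -> np.ndarray:
        """Stack landmarks into an (n_frames, len(names), 3) array."""
        return np.stack([self.landmarks[n] for n in names], axis=1)

    def copy(self) -> "TrackedTrial":
        return TrackedTrial(
            frame_rate=self.frame_rate,
            times=self.times.copy(),
            landmarks={k: v.copy() for k, v in self.landmarks.items()},
            substrate=self.substrate,
            instar=self.instar,
            body_length=self.body_length,
            mass=self.mass,
            meta=dict(self.meta),
        )


@dataclasses.dataclass(frozen=True)
class RodSegment:
    length: float  # m
    mass: float  # kg

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.mass > 0):
            raise ValueError("rod segment length and mass must be positive")


@dataclasses.dataclass(frozen=True)
class LegMorphometrics:
    """Two-segment rod model of the six legs.

    ``segment_1`` is the distal tibia+tarsus rod, ``segment_2`` the
    proximal femur+trochanter+coxa rod, per leg L1..R3.
    """

    segment_1: Mapping[str, RodSegment]
    segment_2: Mapping[str, RodSegment]

    def __post_init__(self) -> None:
        for seg in (self.segment_1, self.segment_2):
            if set(seg) != set(LEG_NAMES):
                raise ValueError(f"morphometrics must cover legs {LEG_NAMES}")

    @property
    def total_leg_mass(self) -> float:
        return sum(s.mass for s in self.segment_1.values()) + sum(
            s.mass for s in self.segment_2.values()
        )


def _unit_factor(units: str) -> float:
    try:
        return {"m": 1.0, "mm": 1e-3}[units]
    except KeyError:
        raise FormatError(f"unknown length unit {units!r}; use 'm' or 'mm'")


def read_landmark_table(
    path,
    schema: Sequence[str] = MINIMAL_LANDMARKS,
    units: str = "mm",
    frame_rate: float | None = None,
    **trial_kwargs,
) -> TrackedTrial:
    """Read a landmark trajectory CSV into a :class:`TrackedTrial`.

    Parameters
    ----------
    path : path-like
        CSV with columns ``frame,time_s,<name>_X,<name>_Y,<name>_Z``.
    schema : sequence of str
        Landmark names that must be present; extra columns are read too.
    units : {'mm', 'm'}
        Length unit of the coordinate columns; converted to metres.
    frame_rate : float, optional
        Override; by default inferred from the time column.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError("landmark table must have a 'time_s' column")
    present = {
        c[: -len("_X")] for c in df.columns if c.endswith("_X")
    }
    missing = [name for name in schema if name not in present]
    if missing:
        raise SchemaError(
            "missing landmark column(s): " + ", ".join(sorted(missing))
        )
    factor = _unit_factor(units)
    times = df["time_s"].to_numpy(dtype=float)
    if frame_rate is None:
        if times.size < 2:
            raise FormatError("cannot infer frame rate from <2 frames")
        frame_rate = 1.0 / float(np.mean(np.diff(times)))
    landmarks = {}
    for name in sorted(present):
        cols = [f"{name}_{ax}" for ax in "XYZ"]
        for c in cols:
            if c not in df.columns:
                raise SchemaError(f"missing landmark column(s): {name} ({c})")
        landmarks[name] = df[cols].to_numpy(dtype=float) * factor
    return TrackedTrial(
        frame_rate=frame_rate, times=times, landmarks=landmarks, **trial_kwargs
    )


def write_landmark_table(trial: TrackedTrial, path, units: str = "mm") -> None:
    """Write a trial back to the flat CSV dialect (inverse of the reader)."""
    factor = _unit_factor(units)
    data: dict[str, np.ndarray] = {
        "frame": np.arange(trial.n_frames),
        "time_s": trial.times,
    }
    for name in sorted(trial.landmarks):
        xyz = trial.landmarks[name] / factor
        for i, ax in enumerate("XYZ"):
            data[f"{name}_{ax}"] = xyz[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_body_mesh(path, units: str = "mm") -> trimesh.Trimesh:
    """Load a watertight STL body mesh, returning vertices in metres.

    The mesh is vertex-merged, checked for watertightness, and reoriented
    so that faces point outward (signed volume > 0).

    Raises
    ------
    GeometryError
        If the mesh is not watertight after merging (the open-edge count is
        reported) or has zero volume.
    """
    mesh = trimesh.load_mesh(str(path), process=True)
    mesh.merge_vertices()
    if not mesh.is_watertight:
        n_open = len(
            trimesh.grouping.group_rows(mesh.edges_sorted, require_count=1)
        )
        raise GeometryError(f"mesh is not watertight: {n_open} open edge(s)")
    if not mesh.is_winding_consistent or mesh.volume < 0:
        trimesh.repair.fix_normals(mesh)
    if abs(mesh.volume) <= 0:
        raise GeometryError("mesh has zero volume")
    if mesh.volume < 0:
        mesh.invert()
    mesh.apply_scale(_unit_factor(units))
    return mesh


def _morph_from_dict(d: Mapping) -> LegMorphometrics:
    seg1, seg2 = {}, {}
    for leg in LEG_NAMES:
        entry = d[leg]
        seg1[leg] = RodSegment(
            length=float(entry["segment_1"]["length_mm"]) * 1e-3,
            mass=float(entry["segment_1"]["mass_mg"]) * 1e-6,
        )
        seg2[leg] = RodSegment(
            length=float(entry["segment_2"]["length_mm"]) * 1e-3,
            mass=float(entry["segment_2"]["mass_mg"]) * 1e-6,
        )
    return LegMorphometrics(segment_1=seg1, segment_2=seg2)


def read_morphometrics(path) -> LegMorphometrics:
    """Read per-leg two-segment lengths/masses from a YAML config."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return _morph_from_dict(d["legs"] if "legs" in d else d)


def default_morphometrics() -> LegMorphometrics:
    """Package default leg morphometrics for the standardized nymph."""
    path = Path(__file__).parent / "data" / "leg_morphometrics.yaml"
    return read_morphometrics(path)


def write_metrics(series: pd.DataFrame, path) -> None:
    """Write a per-frame metric table as plain CSV.

    One row per frame, deterministic column order (as given), full float
    precision; NaN cells are serialized as empty fields.
    """
    series.to_csv(path, index=False, float_format="%.17g", na_rep="")


def read_metrics(path) -> pd.DataFrame:
    """Read back a metrics CSV; empty cells become NaN."""
    return pd.read_csv(path)
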