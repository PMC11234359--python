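"""Position/orientation collective variables for a two-protein complex.

Six internal coordinates describe where a ligand protein sits relative to a
receptor protein and how it is oriented.  Each protein contributes three
mass-weighted reference points computed from backbone selections: T1-T3 for
the receptor (enzyme) and B1-B3 for the ligand.  The coordinates are

* ``r``       - T1-B1 centre-of-mass distance (nm), the main coordinate,
* ``theta_p`` - angle T2-T1-B1 (rad), position of the ligand,
* ``phi_p``   - dihedral T3-T2-T1-B1 (rad), position of the ligand,
* ``theta_o`` - angle T1-B1-B2 (rad), orientation of the ligand,
* ``phi_o``   - dihedral T2-T1-B1-B2 (rad), orientation,
* ``psi_o``   - dihedral T1-B3-B1-B2 (rad), orientation.

All six are functions of internal geometry only and therefore invariant
under global rigid-body motion.  Angles are stored in radians; dihedrals
follow the IUPAC sign convention (clockwise positive looking from the
second to the third point) and lie in (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .structure_io import (
    Atom,
    SelectionSpec,
    Structure,
    Trajectory,
    masses_of,
    select_atoms,
)

__all__ = [
    "ReferencePointSpec",
    "ReferencePoints",
    "CVFrame",
    "CVSeries",
    "center_of_mass",
    "angle",
    "dihedral",
    "compute_reference_points",
    "compute_cv_frame",
    "compute_cv_series",
]

_DEGENERACY_TOL = 1e-10


class GeometryError(ValueError):
    """Degenerate geometry (coincident or collinear defining points)."""


def center_of_mass(coordinates: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position of a group of atoms (nm)."""
    coordinates = np.asarray(coordinates, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coordinates.ndim != 2 or coordinates.shape[0] == 0:
        raise GeometryError("center of mass of an empty group is undefined")
    if masses.shape[0] != coordinates.shape[0]:
        raise GeometryError("mass array does not match coordinate array")
    return np.average(coordinates, axis=0, weights=masses)


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex *b*, in [0, pi]."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _DEGENERACY_TOL or nv < _DEGENERACY_TOL:
        raise GeometryError("angle undefined: coincident points")
    cosine = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(cosine))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion a-b-c-d in (-pi, pi], IUPAC convention.

    Looking down the b->c axis, a clockwise rotation of the far bond (c->d)
    relative to the near bond (b->a) is positive.
    """
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < _DEGENERACY_TOL:
        raise GeometryError("dihedral undefined: central points coincide")
    if np.linalg.norm(n1) < _DEGENERACY_TOL or np.linalg.norm(n2) < _DEGENERACY_TOL:
        raise GeometryError("dihedral undefined: three defining points are collinear")
    m1 = np.cross(n1, b2 / nb2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    value = float(np.arctan2(y, x))
    if value <= -np.pi + 1e-15:  # map -pi onto +pi so the range is (-pi, pi]
        value = np.pi
    return value


@dataclass(frozen=True)
class ReferencePointSpec:
    """Selections defining the six reference points.

    Defaults (factory :meth:`trypsin_bpti`) follow the trypsin-BPTI setup:
    whole-backbone centres of mass for T1/B1 and short well-structured
    backbone segments for the others (T2 = Val233-Ala241 and
    T3 = Gln46-Leu67 of trypsin; B2 = Ala48-Thr54 and B3 = Cys14-Ala16 of
    the inhibitor).
    """

    T1: SelectionSpec
    T2: SelectionSpec
    T3: SelectionSpec
    B1: SelectionSpec
    B2: SelectionSpec
    B3: SelectionSpec

    def __post_init__(self) -> None:
        specs = [self.T1, self.T2, self.T3, self.B1, self.B2, self.B3]
        if len(set(specs)) != 6:
            raise ValueError("the six reference-point selections must be pairwise distinct")

    @classmethod
    def trypsin_bpti(cls, enzyme_chain: str = "E", ligand_chain: str = "I") -> "ReferencePointSpec":
        return cls(
            T1=SelectionSpec(enzyme_chain, None, "backbone"),
            T2=SelectionSpec(enzyme_chain, (233, 241), "backbone"),
            T3=SelectionSpec(enzyme_chain, (46, 67), "backbone"),
            B1=SelectionSpec(ligand_chain, None, "backbone"),
            B2=SelectionSpec(ligand_chain, (48, 54), "backbone"),
            B3=SelectionSpec(ligand_chain, (14, 16), "backbone"),
        )

    def point_names(self) -> tuple[str, ...]:
        return ("T1", "T2", "T3", "B1", "B2", "B3")


@dataclass(frozen=True)
class ReferencePoints:
    """The six reference-point positions (nm) for one frame."""

    T1: np.ndarray
    T2: np.ndarray
    T3: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    B3: np.ndarray


@dataclass(frozen=True)
class CVFrame:
    """The six collective variables for one frame."""

    r: float
    theta_p: float
    phi_p: float
    theta_o: float
    phi_o: float
    psi_o: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.theta_p, self.phi_p, self.theta_o, self.phi_o, self.psi_o])


CV_COLUMNS = ["r_nm", "theta_p_rad", "phi_p_rad", "theta_o_rad", "phi_o_rad", "psi_o_rad"]
CV_NAMES = ["r", "theta_p", "phi_p", "theta_o", "phi_o", "psi_o"]


@dataclass
class CVSeries:
    """Per-frame collective variables with time stamps."""

    times: np.ndarray
    r: np.ndarray
    theta_p: np.ndarray
    phi_p: np.ndarray
    theta_o: np.ndarray
    phi_o: np.ndarray
    psi_o: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.times, self.r, self.theta_p, self.phi_p, self.theta_o, self.phi_o, self.psi_o]
        lengths = {len(np.asarray(a)) for a in arrays}
        if len(lengths) != 1:
            raise ValueError("all CV series must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> CVFrame:
        return CVFrame(
            float(self.r[i]), float(self.theta_p[i]), float(self.phi_p[i]),
            float(self.theta_o[i]), float(self.phi_o[i]), float(self.psi_o[i]),
        )

    def to_dataframe(self, degrees: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_ps": self.times,
                "r_nm": self.r,
                "theta_p_rad": self.theta_p,
                "phi_p_rad": self.phi_p,
                "theta_o_rad": self.theta_o,
                "phi_o_rad": self.phi_o,
                "psi_o_rad": self.psi_o,
            }
        )
        if degrees:
            for col in df.columns[2:]:
                df[col.replace("_rad", "_deg")] = np.degrees(df[col])
        return df

    def write_csv(self, path: str | Path, degrees: bool = False) -> None:
        self.to_dataframe(degrees=degrees).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "CVSeries":
        df = pd.read_csv(path)
        return cls(
            times=df["time_ps"].to_numpy(),
            r=df["r_nm"].to_numpy(),
            theta_p=df["theta_p_rad"].to_numpy(),
            phi_p=df["phi_p_rad"].to_numpy(),
            theta_o=df["theta_o_rad"].to_numpy(),
            phi_o=df["phi_o_rad"].to_numpy(),
            psi_o=df["psi_o_rad"].to_numpy(),
        )


def _resolve_groups(
    topology: Sequence[Atom], spec: ReferencePointSpec
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Resolve each reference point's atom indices and masses, naming failures."""
    groups = {}
    for name in spec.point_names():
        sel = getattr(spec, name)
        try:
            idx = select_atoms(list(topology), sel)
        except Exception as exc:
            raise type(exc)(f"reference point {name}: {exc}") from exc
        groups[name] = (idx, masses_of(topology)[idx])
    return groups


def _points_from_groups(coords: np.ndarray, groups) -> ReferencePoints:
    pts = {
        name: center_of_mass(coords[idx], m) for name, (idx, m) in groups.items()
    }
    return ReferencePoints(**pts)


def _cv_from_points(p: ReferencePoints) -> CVFrame:
    r = float(np.linalg.norm(p.B1 - p.T1))
    if r <= 0:
        raise GeometryError("T1 and B1 coincide; r undefined")
    return CVFrame(
        r=r,
        theta_p=angle(p.T2, p.T1, p.B1),
        phi_p=dihedral(p.T3, p.T2, p.T1, p.B1),
        theta_o=angle(p.T1, p.B1, p.B2),
        phi_o=dihedral(p.T2, p.T1, p.B1, p.B2),
        psi_o=dihedral(p.T1, p.B3, p.B1, p.B2),
    )


def _check_box(points: ReferencePoints, box_length: float | None) -> None:
    if box_length is None:
        return
    arr = np.stack([points.T1, points.T2, points.T3, points.B1, points.B2, points.B3])
    dists = np.linalg.norm(arr[:, None, :] - arr[None, :, :], axis=-1)
    if np.any(dists > box_length / 2):
        raise GeometryError(
            "inter-point distance exceeds half the box length; coordinates appear "
            "wrapped — provide whole-molecule (unwrapped) input"
        )


def compute_reference_points(structure: Structure, spec: ReferencePointSpec) -> ReferencePoints:
    groups = _resolve_groups(structure.topology, spec)
    return _points_from_groups(structure.coordinates, groups)


def compute_cv_frame(
    structure: Structure, spec: ReferencePointSpec, box_length: float | None = None
) -> CVFrame:
    points = compute_reference_points(structure, spec)
    _check_box(points, box_length)
    return _cv_from_points(points)


def compute_cv_series(
    trajectory: Trajectory, spec: ReferencePointSpec, box_length: float | None = None
) -> CVSeries:
    """Compute all six collective variables for every frame of a trajectory."""
    groups = _resolve_groups(trajectory.topology, spec)
    records = np.empty((trajectory.n_frames, 6))
    for i, frame in enumerate(trajectory.frames):
        points = _points_from_groups(frame.coordinates, groups)
        _check_box(points, box_length)
        records[i] = _cv_from_points(points).as_array()
    return CVSeries(
        times=trajectory.times,
        r=records[:, 0],
        theta_p=records[:, 1],
        phi_p=records[:, 2],
        theta_o=records[:, 3],
        phi_o=records[:, 4],
        psi_o=records[:, 5],
    )
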