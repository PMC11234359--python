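"""Interface interaction measurements on structures and trajectories.

Four families of measurements characterise a protein-protein interface:

* heavy-atom contacts — present when the minimum inter-selection heavy-atom
  distance is strictly below a cutoff (0.35 nm by default), histogrammed
  along the centre-of-mass distance for dissociation runs;
* hydrogen bonds — the Wernet-Nilsson distance-angle cone,
  ``r_DA < 3.3 A - 0.00044 A/deg^2 * delta_HDA^2`` (0.2904 nm at 30
  degrees), with the hydrogen-donor-acceptor angle in degrees, evaluated
  over all N/O donors
  carrying a hydrogen and all N/O acceptors;
* two special distances — the minimum of the three arginine guanidine
  nitrogen distances to a partner atom, and the distance from an aromatic
  ring centroid (six ring carbons, unweighted) to a target atom, used to
  read out cation-pi geometry;
* solvent-accessible surface area — the Shrake-Rupley sphere-point method
  (golden-spiral placement, 960 points and a 0.14 nm probe by default) with
  per-residue sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import (
    Atom,
    SelectionSpec,
    Structure,
    StructureError,
    Trajectory,
    select_atoms,
    vdw_radii_of,
)
from .collective_variables import CVSeries

__all__ = [
    "ContactDefinition",
    "HBondRecord",
    "HBondFrequencyTable",
    "SASAResult",
    "contact_present",
    "contact_histogram_along_r",
    "detect_hbonds",
    "hbond_frequencies",
    "min_guanidine_distance",
    "ring_centroid_distance",
    "sasa",
    "wernet_nilsson_max_distance",
]

WN_R_MAX_NM = 0.33
WN_ANGLE_COEFF = 0.00044 * 0.1  # 0.00044 A/deg^2, converted to nm/deg^2
CONTACT_CUTOFF_NM = 0.35
GUANIDINE_NITROGENS = ("NE", "NH1", "NH2")
RING_CARBONS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
MAX_DH_BOND_NM = 0.13  # hydrogen considered bonded to its donor within this

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

#: donors whose label collapses to "s" (side-chain guanidine / ammonium)
_S_LABEL_ATOMS = {("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("LYS", "NZ")}


def wernet_nilsson_max_distance(delta_hda_deg: np.ndarray) -> np.ndarray:
    """Donor-acceptor distance bound of the cone criterion at a given angle."""
    return WN_R_MAX_NM - WN_ANGLE_COEFF * np.asarray(delta_hda_deg, dtype=float) ** 2


def _resolve(structure: Structure, selection) -> np.ndarray:
    if isinstance(selection, SelectionSpec):
        return select_atoms(structure, selection)
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise StructureError("empty atom selection")
    return idx


@dataclass(frozen=True)
class ContactDefinition:
    """A labelled heavy-atom contact between two selections."""

    partner_a: object  # SelectionSpec or index sequence
    partner_b: object
    cutoff_nm: float = CONTACT_CUTOFF_NM
    label: str = ""

    def __post_init__(self) -> None:
        if self.cutoff_nm <= 0:
            raise ValueError("contact cutoff must be positive")


def contact_present(structure: Structure, definition: ContactDefinition) -> tuple[bool, float]:
    """Whether the contact is formed, plus the minimum pair distance (nm).

    A contact requires the minimum heavy-atom inter-selection distance to be
    *strictly* below the cutoff.  Hydrogens in the selections are ignored.
    """
    idx_a = _resolve(structure, definition.partner_a)
    idx_b = _resolve(structure, definition.partner_b)
    top = structure.topology
    idx_a = idx_a[[not top[i].is_hydrogen for i in idx_a]]
    idx_b = idx_b[[not top[i].is_hydrogen for i in idx_b]]
    if idx_a.size == 0 or idx_b.size == 0:
        raise StructureError("contact selection contains no heavy atoms")
    dmin = float(cdist(structure.coordinates[idx_a], structure.coordinates[idx_b]).min())
    return dmin < definition.cutoff_nm, dmin


def contact_histogram_along_r(
    trajectory: Trajectory,
    definitions: Sequence[ContactDefinition],
    cv_series: CVSeries,
    r_bin_edges: np.ndarray,
) -> pd.DataFrame:
    """Per-definition contact frequency in bins of the centre-of-mass distance.

    For each r-bin the frequency is the fraction of that bin's frames in
    which the contact is present.  Bins containing no frames are reported
    with ``n_frames = 0`` and frequency NaN (flagged, not zero-filled).
    """
    if len(cv_series) != trajectory.n_frames:
        raise ValueError(
            f"CV series ({len(cv_series)}) not aligned with trajectory ({trajectory.n_frames})"
        )
    edges = np.asarray(r_bin_edges, dtype=float)
    bin_index = np.digitize(cv_series.r, edges) - 1
    n_bins = len(edges) - 1
    present = np.zeros((trajectory.n_frames, len(definitions)), dtype=bool)
    for f in range(trajectory.n_frames):
        frame_structure = trajectory[f]
        for d, definition in enumerate(definitions):
            present[f, d], _ = contact_present(frame_structure, definition)
    rows = []
    for d, definition in enumerate(definitions):
        for b in range(n_bins):
            mask = bin_index == b
            n = int(mask.sum())
            rows.append(
                {
                    "label": definition.label or f"contact_{d}",
                    "r_lo": edges[b],
                    "r_hi": edges[b + 1],
                    "n_frames": n,
                    "frequency": float(present[mask, d].mean()) if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Hydrogen bonds
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HBondRecord:
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    r_da_nm: float
    delta_hda_deg: float
    label: str


def _donor_label(atom: Atom) -> str:
    if (atom.residue_name, atom.name) in _S_LABEL_ATOMS:
        suffix = "s"
    else:
        suffix = atom.name
    one = THREE_TO_ONE.get(atom.residue_name, "X")
    return f"{one}{atom.residue_index}-{suffix}"


def _acceptor_label(atom: Atom) -> str:
    one = THREE_TO_ONE.get(atom.residue_name, "X")
    return f"{one}{atom.residue_index}-{atom.name}"


def _donor_hydrogen_pairs(structure: Structure) -> list[tuple[int, int]]:
    """(donor, hydrogen) pairs: N/O heavy atoms with a same-residue H within bond range."""
    top = structure.topology
    coords = structure.coordinates
    pairs = []
    by_residue: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(top):
        by_residue.setdefault((a.chain_id, a.residue_index), []).append(i)
    for members in by_residue.values():
        hydrogens = [i for i in members if top[i].is_hydrogen]
        heavies = [i for i in members if top[i].element in ("N", "O")]
        if not hydrogens or not heavies:
            continue
        d = cdist(coords[hydrogens], coords[heavies])
        for hi, h_idx in enumerate(hydrogens):
            j = int(np.argmin(d[hi]))
            if d[hi, j] <= MAX_DH_BOND_NM:
                pairs.append((heavies[j], h_idx))
    return pairs


def detect_hbonds(structure: Structure) -> list[HBondRecord]:
    """All hydrogen bonds in a frame under the Wernet-Nilsson criterion.

    Donors are protein N/O atoms carrying a hydrogen (paired geometrically
    within the residue); acceptors are all N/O atoms.  Pairs within the same
    residue are excluded.  Raises if the topology has no hydrogens, since
    the criterion needs explicit hydrogen positions (protonate first).
    """
    top = structure.topology
    if not any(a.is_hydrogen for a in top):
        raise StructureError(
            "no hydrogens in topology; the hydrogen-bond criterion requires a "
            "protonated structure"
        )
    coords = structure.coordinates
    dh_pairs = _donor_hydrogen_pairs(structure)
    if not dh_pairs:
        return []
    acceptors = np.array([i for i, a in enumerate(top) if a.element in ("N", "O")])
    donors = np.array([d for d, _ in dh_pairs])
    hydros = np.array([h for _, h in dh_pairs])

    r_da = cdist(coords[donors], coords[acceptors])  # (n_don, n_acc)
    # angle H-D-A at the donor
    dh = coords[hydros] - coords[donors]
    dh /= np.linalg.norm(dh, axis=1, keepdims=True)
    da = coords[acceptors][None, :, :] - coords[donors][:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        da_unit = da / np.linalg.norm(da, axis=2, keepdims=True)
    cos_delta = np.clip(np.einsum("dk,dak->da", dh, da_unit), -1.0, 1.0)
    delta_deg = np.degrees(np.arccos(cos_delta))

    same_residue = np.array(
        [
            [
                top[d].chain_id == top[a].chain_id and top[d].residue_index == top[a].residue_index
                for a in acceptors
            ]
            for d in donors
        ]
    )
    bonded = (r_da < wernet_nilsson_max_distance(delta_deg)) & ~same_residue
    records = []
    for di, ai in zip(*np.nonzero(bonded)):
        d_idx, h_idx, a_idx = int(donors[di]), int(hydros[di]), int(acceptors[ai])
        label = f"{_donor_label(top[d_idx])}–{_acceptor_label(top[a_idx])}"
        records.append(
            HBondRecord(d_idx, h_idx, a_idx, float(r_da[di, ai]), float(delta_deg[di, ai]), label)
        )
    return records


@dataclass
class HBondFrequencyTable:
    """Relative population of each labelled donor-acceptor pair over frames."""

    frequencies: pd.Series  # index: label, values in [0, 1]
    n_frames: int
    report_threshold: float = 0.1

    def filtered(self) -> pd.Series:
        return self.frequencies[self.frequencies >= self.report_threshold]

    def get(self, label: str) -> float:
        return float(self.frequencies.get(label, 0.0))


def hbond_frequencies(
    trajectory: Trajectory,
    chain_a: str,
    chain_b: str,
    report_threshold: float = 0.1,
) -> HBondFrequencyTable:
    """Fraction of frames in which each inter-partner hydrogen bond is present.

    Only bonds whose donor and acceptor sit on different chains (one in
    *chain_a*, one in *chain_b*) are counted.  Side-chain guanidine /
    ammonium donors share one "s" label per residue, so their frequency is
    the frame-wise OR of the individual nitrogen donors.
    """
    counts: dict[str, int] = {}
    top = trajectory.topology
    for f in range(trajectory.n_frames):
        frame_labels = set()
        for rec in detect_hbonds(trajectory[f]):
            cd = top[rec.donor_index].chain_id
            ca = top[rec.acceptor_index].chain_id
            if {cd, ca} == {chain_a, chain_b}:
                frame_labels.add(rec.label)
        for label in frame_labels:
            counts[label] = counts.get(label, 0) + 1
    n = trajectory.n_frames
    freqs = pd.Series({k: v / n for k, v in counts.items()}, dtype=float).sort_values(
        ascending=False
    )
    return HBondFrequencyTable(freqs, n, report_threshold)


# --------------------------------------------------------------------------
# Guanidine and aromatic-ring distances
# --------------------------------------------------------------------------


def _residue_atom_indices(structure: Structure, chain_id: str, residue_index: int) -> dict[str, int]:
    return {
        a.name: i
        for i, a in enumerate(structure.topology)
        if a.chain_id == chain_id and a.residue_index == residue_index
    }


def min_guanidine_distance(
    structure: Structure, chain_id: str, residue_index: int, target_index: int
) -> float:
    """Minimum distance (nm) from an arginine's three guanidine N to a target atom."""
    atoms = _residue_atom_indices(structure, chain_id, residue_index)
    residue_names = {
        a.residue_name
        for a in structure.topology
        if a.chain_id == chain_id and a.residue_index == residue_index
    }
    if residue_names != {"ARG"}:
        raise StructureError(
            f"residue {chain_id}/{residue_index} is {residue_names or 'absent'}, not ARG"
        )
    missing = [n for n in GUANIDINE_NITROGENS if n not in atoms]
    if missing:
        raise StructureError(f"arginine {chain_id}/{residue_index} lacks {missing}")
    target = structure.coordinates[target_index]
    dists = [
        float(np.linalg.norm(structure.coordinates[atoms[n]] - target))
        for n in GUANIDINE_NITROGENS
    ]
    return min(dists)


def ring_centroid(structure: Structure, chain_id: str, residue_index: int) -> np.ndarray:
    """Unweighted centroid of the six aromatic ring carbons of a Tyr/Phe."""
    atoms = _residue_atom_indices(structure, chain_id, residue_index)
    missing = [n for n in RING_CARBONS if n not in atoms]
    if missing:
        raise StructureError(
            f"aromatic residue {chain_id}/{residue_index} lacks ring atoms {missing}"
        )
    idx = [atoms[n] for n in RING_CARBONS]
    return structure.coordinates[idx].mean(axis=0)


def ring_centroid_distance(
    structure: Structure, chain_id: str, residue_index: int, target_index: int
) -> float:
    """Distance (nm) from an aromatic ring centroid to a target atom."""
    centroid = ring_centroid(structure, chain_id, residue_index)
    return float(np.linalg.norm(structure.coordinates[target_index] - centroid))


# --------------------------------------------------------------------------
# Shrake-Rupley solvent-accessible surface area
# --------------------------------------------------------------------------


@dataclass
class SASAResult:
    atom_areas_nm2: np.ndarray
    residue_areas: pd.DataFrame  # chain_id, residue_index, residue_name, area_nm2
    probe_radius_nm: float
    n_sphere_points: int

    def residue_area(self, chain_id: str, residue_index: int) -> float:
        df = self.residue_areas
        row = df[(df.chain_id == chain_id) & (df.residue_index == residue_index)]
        if row.empty:
            raise KeyError(f"residue {chain_id}/{residue_index} not present")
        return float(row.area_nm2.iloc[0])


def _golden_spiral_points(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    structure: Structure,
    probe_radius_nm: float = 0.14,
    n_sphere_points: int = 960,
) -> SASAResult:
    """Shrake-Rupley solvent-accessible surface area, per atom and per residue.

    Each atom's accessible area is the fraction of quasi-uniform test points
    on its probe-inflated sphere that fall outside every neighbour's
    inflated sphere, times the sphere area.  Residue areas are sums over
    member atoms.
    """
    coords = structure.coordinates
    radii = vdw_radii_of(structure.topology) + probe_radius_nm
    n = len(radii)
    unit_points = _golden_spiral_points(n_sphere_points)
    areas = np.zeros(n)
    pair_d = cdist(coords, coords)
    for i in range(n):
        neighbors = np.nonzero((pair_d[i] < radii[i] + radii) & (np.arange(n) != i))[0]
        points = coords[i] + radii[i] * unit_points
        if neighbors.size:
            buried = np.zeros(n_sphere_points, dtype=bool)
            for j in neighbors:
                buried |= np.einsum(
                    "pk,pk->p", points - coords[j], points - coords[j]
                ) < radii[j] ** 2
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_sphere_points
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible / n_sphere_points

    rows = {}
    for i, atom in enumerate(structure.topology):
        key = (atom.chain_id, atom.residue_index, atom.residue_name)
        rows[key] = rows.get(key, 0.0) + areas[i]
    residue_df = pd.DataFrame(
        [
            {"chain_id": c, "residue_index": r, "residue_name": name, "area_nm2": a}
            for (c, r, name), a in rows.items()
        ]
    )
    return SASAResult(areas, residue_df, probe_radius_nm, n_sphere_points)
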