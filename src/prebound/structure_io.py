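"""Protein structures, trajectories and atom selections.

Coordinates are carried in nanometres and times in picoseconds throughout
the package; PDB files (which are in Angstrom) are converted at the I/O
boundary.  Residues keep their author (PDB) numbering, so selections can be
written directly against the residue labels used in the structural
literature (e.g. the trypsin backbone segment Val233-Ala241).

PDB parsing and writing are delegated to :mod:`biotite`; this module wraps
the result in light-weight domain types and adds the selection engine used
to define collective-variable reference groups.  Alternate-location
conformers are resolved by keeping the highest-occupancy conformer.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

ANGSTROM_PER_NM = 10.0

#: Standard atomic masses (amu) and Bondi van-der-Waals radii (nm) for the
#: elements that occur in (fluorinated) proteins.  Unknown elements are an
#: error rather than a guess.
ELEMENT_TABLE: dict[str, tuple[float, float]] = {
    "H": (1.008, 0.120),
    "C": (12.011, 0.170),
    "N": (14.007, 0.155),
    "O": (15.999, 0.152),
    "F": (18.998, 0.147),
    "P": (30.974, 0.180),
    "S": (32.06, 0.180),
    "SE": (78.971, 0.190),
}

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class StructureError(ValueError):
    """Inconsistent structure, topology or trajectory content."""


class PDBParseError(StructureError):
    """A PDB record could not be parsed."""


class SelectionError(StructureError):
    """An atom selection could not be resolved or is empty."""


class UnknownElementError(StructureError):
    """An element is missing from the mass/radius table."""


def infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name (e.g. ``1HB`` -> ``H``)."""
    stripped = re.sub(r"[^A-Za-z]", "", atom_name.strip())
    if not stripped:
        raise UnknownElementError(f"cannot infer element from atom name {atom_name!r}")
    first = stripped[0].upper()
    if first not in ELEMENT_TABLE:
        raise UnknownElementError(
            f"element {first!r} (from atom name {atom_name!r}) not in element table"
        )
    return first


def element_properties(element: str) -> tuple[float, float]:
    """Return ``(mass_amu, vdw_radius_nm)`` for *element*."""
    key = element.strip().upper()
    if key not in ELEMENT_TABLE:
        raise UnknownElementError(f"unknown element {element!r}")
    return ELEMENT_TABLE[key]


@dataclass(frozen=True)
class Atom:
    """One atom of the topology, in author (PDB) numbering."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    mass: float
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise StructureError(f"atom {self.serial}: mass must be positive")
        if self.vdw_radius <= 0:
            raise StructureError(f"atom {self.serial}: vdW radius must be positive")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


def make_atom(
    serial: int,
    name: str,
    residue_name: str,
    residue_index: int,
    chain_id: str,
    element: str | None = None,
) -> Atom:
    """Build an :class:`Atom`, inferring the element from the name if absent."""
    elem = (element or "").strip().upper() or infer_element(name)
    mass, radius = element_properties(elem)
    return Atom(serial, name.strip(), elem, residue_name.strip(), residue_index, chain_id, mass, radius)


@dataclass
class Frame:
    """Coordinates (nm) of all atoms at one point in time (ps)."""

    coordinates: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError("frame coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError("frame contains non-finite coordinates")


@dataclass
class Structure:
    """A topology with a single coordinate frame (e.g. a crystal structure)."""

    topology: list[Atom]
    frame: Frame

    def __post_init__(self) -> None:
        if len(self.topology) != self.frame.coordinates.shape[0]:
            raise StructureError(
                f"topology has {len(self.topology)} atoms but frame has "
                f"{self.frame.coordinates.shape[0]} coordinate rows"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def coordinates(self) -> np.ndarray:
        return self.frame.coordinates


@dataclass
class Trajectory:
    """A constant topology with an ordered sequence of frames."""

    topology: list[Atom]
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = len(self.topology)
        for i, frame in enumerate(self.frames):
            if frame.coordinates.shape[0] != n:
                raise StructureError(f"frame {i} has wrong atom count")
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    @property
    def coordinates(self) -> np.ndarray:
        """All coordinates stacked, shape ``(n_frames, n_atoms, 3)``."""
        return np.stack([f.coordinates for f in self.frames])

    def __getitem__(self, i: int) -> Structure:
        return Structure(self.topology, self.frames[i])


def masses_of(topology: Sequence[Atom]) -> np.ndarray:
    return np.array([a.mass for a in topology], dtype=float)


def vdw_radii_of(topology: Sequence[Atom]) -> np.ndarray:
    return np.array([a.vdw_radius for a in topology], dtype=float)


# --------------------------------------------------------------------------
# Selections
# --------------------------------------------------------------------------

AtomClass = Literal["backbone", "heavy", "all", "named"]


@dataclass(frozen=True)
class SelectionSpec:
    """A chain / residue-range / atom-class selection.

    ``residue_range`` is inclusive on both ends in author numbering; ``None``
    selects the whole chain.  ``atom_class='backbone'`` selects exactly the
    N, CA, C, O atoms of each residue; ``'heavy'`` selects non-hydrogens by
    element; ``'named'`` selects the atom names listed in ``names``.
    """

    chain_id: str
    residue_range: tuple[int, int] | None = None
    atom_class: AtomClass = "backbone"
    names: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.residue_range is not None:
            first, last = self.residue_range
            if first > last:
                raise SelectionError(
                    f"reversed residue range [{first}, {last}] in chain {self.chain_id}"
                )
        if self.atom_class == "named" and not self.names:
            raise SelectionError("atom_class 'named' requires a non-empty name set")


def select_atoms(structure: Structure | Trajectory | Sequence[Atom], spec: SelectionSpec) -> np.ndarray:
    """Resolve *spec* against a topology, returning sorted atom indices.

    Raises :class:`SelectionError` if the chain does not exist or the
    selection is empty — a selection never silently resolves to nothing.
    """
    topology = structure if isinstance(structure, (list, tuple)) else structure.topology
    chains = {a.chain_id for a in topology}
    if spec.chain_id not in chains:
        raise SelectionError(
            f"chain {spec.chain_id!r} not in topology (chains: {sorted(chains)})"
        )
    indices = []
    for i, atom in enumerate(topology):
        if atom.chain_id != spec.chain_id:
            continue
        if spec.residue_range is not None:
            first, last = spec.residue_range
            if not (first <= atom.residue_index <= last):
                continue
        if spec.atom_class == "backbone" and atom.name not in BACKBONE_NAMES:
            continue
        if spec.atom_class == "heavy" and atom.is_hydrogen:
            continue
        if spec.atom_class == "named" and atom.name not in spec.names:
            continue
        indices.append(i)
    if not indices:
        raise SelectionError(f"selection {spec} resolved to zero atoms")
    return np.array(indices, dtype=int)


# --------------------------------------------------------------------------
# PDB reading / writing (via biotite)
# --------------------------------------------------------------------------


def _validate_pdb_records(path: Path) -> None:
    """Cheap pre-check so malformed coordinate records fail naming the line."""
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                n_records += 1
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"{path}:{lineno}: truncated coordinate record")
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError as exc:
                    raise PDBParseError(
                        f"{path}:{lineno}: unparseable coordinate field: {line.rstrip()!r}"
                    ) from exc
    if n_records == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")


def _topology_from_atom_array(arr) -> list[Atom]:
    topology = []
    serials = getattr(arr, "atom_id", None)
    for i in range(arr.array_length()):
        serial = int(serials[i]) if serials is not None else i + 1
        topology.append(
            make_atom(
                serial=serial,
                name=str(arr.atom_name[i]),
                residue_name=str(arr.res_name[i]),
                residue_index=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                element=str(arr.element[i]),
            )
        )
    return topology


def read_pdb(path: str | Path, keep_hetero: bool = False) -> Structure:
    """Read a single-model PDB file into a :class:`Structure`.

    HETATM records (cosolutes, ions, waters) are excluded by default;
    pass ``keep_hetero=True`` to retain them.  For files with alternate
    locations the highest-occupancy conformer is kept.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_records(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # element-guess notices
        pdb = PDBFile.read(path)
        arr = pdb.get_structure(model=1, altloc="occupancy", extra_fields=["atom_id"])
    if not keep_hetero:
        arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise PDBParseError(f"{path}: no atoms left after HETATM filtering")
    topology = _topology_from_atom_array(arr)
    coords_nm = np.asarray(arr.coord, dtype=float) / ANGSTROM_PER_NM
    return Structure(topology, Frame(coords_nm, time=0.0))


def _atom_array_from(topology: Sequence[Atom], coords_nm: np.ndarray):
    import biotite.structure as struc

    n = len(topology)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords_nm, dtype=float) * ANGSTROM_PER_NM
    arr.chain_id = np.array([a.chain_id for a in topology])
    arr.res_id = np.array([a.residue_index for a in topology])
    arr.res_name = np.array([a.residue_name for a in topology])
    arr.atom_name = np.array([a.name for a in topology])
    arr.element = np.array([a.element for a in topology])
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_pdb(structure: Structure | Trajectory, path: str | Path) -> None:
    """Write a structure (one MODEL) or trajectory (multi-MODEL) as PDB, in Angstrom."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(structure, Trajectory):
        arrays = [_atom_array_from(structure.topology, f.coordinates) for f in structure.frames]
        payload = struc.stack(arrays)
    else:
        payload = _atom_array_from(structure.topology, structure.frame.coordinates)
    pdb = PDBFile()
    pdb.set_structure(payload)
    pdb.write(str(path))


def read_trajectory(
    path: str | Path,
    topology: Sequence[Atom] | None = None,
    stride_ps: float = 2.0,
) -> Trajectory:
    """Read a trajectory from a multi-MODEL PDB or the package's CSV dialect.

    Frame times are not stored in PDB files, so they are populated as
    ``0, stride, 2*stride, ...`` using *stride_ps* (the study extracted
    biased-run snapshots every 2 ps, which is the default).  If *topology*
    is given, the file's atom count must match it.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_trajectory_csv(path, topology)
    from biotite.structure.io.pdb import PDBFile

    _validate_pdb_records(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pdb = PDBFile.read(path)
        stack = pdb.get_structure(altloc="occupancy", extra_fields=["atom_id"])
    stack = stack[..., ~stack.hetero]
    file_topology = _topology_from_atom_array(stack[0])
    if topology is not None:
        if len(topology) != len(file_topology):
            raise StructureError(
                f"trajectory has {len(file_topology)} atoms but topology has {len(topology)}"
            )
        file_topology = list(topology)
    frames = [
        Frame(np.asarray(stack.coord[i], dtype=float) / ANGSTROM_PER_NM, time=i * stride_ps)
        for i in range(stack.stack_depth())
    ]
    return Trajectory(file_topology, frames)


# --------------------------------------------------------------------------
# Columnar trajectory dialect ("PBTRAJ"): a plain-text format for synthetic
# trajectories.  Version-tagged header, then one CSV row per frame:
# time_ps, x_0, y_0, z_0, x_1, ... in nm.
# --------------------------------------------------------------------------

_PBTRAJ_MAGIC = "# PBTRAJ 1"


def write_trajectory_csv(trajectory: Trajectory, path: str | Path) -> None:
    n = trajectory.n_atoms
    rows = np.column_stack(
        [trajectory.times, trajectory.coordinates.reshape(trajectory.n_frames, 3 * n)]
    )
    header = f"{_PBTRAJ_MAGIC}\n# natoms={n}\n"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, rows, delimiter=",", fmt="%.10g")


def read_trajectory_csv(path: str | Path, topology: Sequence[Atom] | None = None) -> Trajectory:
    path = Path(path)
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _PBTRAJ_MAGIC:
            raise PDBParseError(f"{path}: not a PBTRAJ v1 file (header {magic!r})")
        natoms_line = fh.readline().strip()
        m = re.match(r"# natoms=(\d+)$", natoms_line)
        if not m:
            raise PDBParseError(f"{path}: malformed natoms header {natoms_line!r}")
        n = int(m.group(1))
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.shape[1] != 1 + 3 * n:
        raise StructureError(f"{path}: expected {1 + 3 * n} columns, found {data.shape[1]}")
    if topology is not None and len(topology) != n:
        raise StructureError(f"{path}: file has {n} atoms but topology has {len(topology)}")
    if topology is None:
        topology = [
            make_atom(i + 1, "CA", "GLY", i + 1, "A", element="C") for i in range(n)
        ]
    frames = [Frame(row[1:].reshape(n, 3), time=row[0]) for row in data]
    return Trajectory(list(topology), frames)
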