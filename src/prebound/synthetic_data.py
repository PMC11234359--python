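"""Synthetic inputs for the whole pipeline: no downloads, full ground truth.

Three generators emulate the data the analysis operates on:

* :func:`generate_two_state_trajectory` - rigid-body trajectories of a small
  synthetic two-chain complex whose centre-of-mass distance ``r`` and
  positional coordinates (theta_p, phi_p) follow planned per-state Gaussians
  (defaults: fully bound 2.65 +/- 0.04 nm, prebound 2.85 +/- 0.05 nm), with
  orientational jitter and state-dependent planted interactions (a
  side-chain hydrogen bond, a cation-pi contact and a heavy-atom contact).
* :func:`generate_umbrella_samples` - exact inverse-CDF samples from the
  biased Boltzmann distribution of an analytic free-energy profile, for
  validating the WHAM estimator.
* :func:`generate_dwell_series` - piecewise Ornstein-Uhlenbeck r(t) series
  with planted dwell segments, for validating the state detector.

Every generator is seeded (NumPy PCG64) and returns machine-readable ground
truth next to the data.

The packaged template (:func:`make_template_complex`) is a *synthetic*
two-chain mini-complex (40 + 30 residues) built programmatically: a compact
pseudo-protein per chain with full backbones, a tyrosine ring, an arginine
guanidine group and backbone amide donors, so that every interaction
measurement in the package has a natural target.  It is a geometric
stand-in, not a real structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure_io import (
    Atom,
    Frame,
    SelectionSpec,
    Structure,
    StructureError,
    Trajectory,
    make_atom,
    masses_of,
    select_atoms,
)
from .collective_variables import (
    ReferencePointSpec,
    center_of_mass,
    compute_reference_points,
)

RECEPTOR_CHAIN = "E"
LIGAND_CHAIN = "I"

# Bound-pose positional coordinates of the template complex.  r echoes the
# bound-state centre-of-mass distance of the trypsin-BPTI system; the two
# angular values are arbitrary non-degenerate choices.
BOUND_R = 2.65
BOUND_THETA_P = 1.80
BOUND_PHI_P = 0.60


# --------------------------------------------------------------------------
# Template construction
# --------------------------------------------------------------------------


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on a sphere (golden-spiral placement)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return radius * np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _chain_body(
    chain_id: str,
    first_residue: int,
    n_residues: int,
    radius: float,
    serial_start: int,
) -> tuple[list[Atom], list[np.ndarray]]:
    """A compact pseudo-protein: backbone N/CA/C/O plus an amide H per residue.

    CA atoms sit on a spherical golden spiral; the other backbone atoms are
    placed in a local tangent frame with roughly physical bond lengths.  The
    geometry is schematic (no Ramachandran realism) but non-clashing and
    selection-complete.
    """
    ca = _fibonacci_sphere(n_residues, radius)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = serial_start
    for i in range(n_residues):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - np.array([0.38, 0, 0])
        next_ca = ca[i + 1] if i < n_residues - 1 else ca[i] + np.array([0.38, 0, 0])
        t = next_ca - prev_ca
        t = t / np.linalg.norm(t)
        u = ca[i] / np.linalg.norm(ca[i])  # outward normal
        u = u - np.dot(u, t) * t
        u = u / np.linalg.norm(u)
        res_id = first_residue + i
        n_pos = ca[i] - 0.1458 * t
        c_pos = ca[i] + 0.1525 * t
        o_pos = c_pos + 0.123 * u
        h_pos = n_pos - 0.101 * u
        for name, pos in (("N", n_pos), ("CA", ca[i]), ("C", c_pos), ("O", o_pos), ("H", h_pos)):
            atoms.append(make_atom(serial, name, "ALA", res_id, chain_id))
            coords.append(pos)
            serial += 1
    return atoms, coords


def _rename_residue(atoms: list[Atom], chain_id: str, res_id: int, new_name: str) -> None:
    for i, a in enumerate(atoms):
        if a.chain_id == chain_id and a.residue_index == res_id:
            atoms[i] = replace(a, residue_name=new_name)


def _residue_frame(atoms: Sequence[Atom], coords: np.ndarray, chain_id: str, res_id: int):
    """Outward-pointing local frame (origin=CA, normal=u) of a residue."""
    idx = {
        a.name: i
        for i, a in enumerate(atoms)
        if a.chain_id == chain_id and a.residue_index == res_id
    }
    ca = coords[idx["CA"]]
    u = ca / np.linalg.norm(ca)
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return ca, u, e1, e2


def _append_tyrosine_ring(
    atoms: list[Atom], coords: list[np.ndarray], chain_id: str, res_id: int
) -> None:
    """Attach CB + an aromatic ring (CG..CZ) + OH to an existing residue."""
    _rename_residue(atoms, chain_id, res_id, "TYR")
    ca, u, e1, e2 = _residue_frame(atoms, np.asarray(coords), chain_id, res_id)
    cb = ca + 0.153 * u
    centroid = cb + 0.28 * u
    ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    serial = max(a.serial for a in atoms) + 1
    atoms.append(make_atom(serial, "CB", "TYR", res_id, chain_id))
    coords.append(cb)
    serial += 1
    # ring lies tangent to the body surface so its normal points outward
    # (keeps the solvent-side face clear for planted cation-pi partners)
    for k, name in enumerate(ring_names):
        ang = k * np.pi / 3
        pos = centroid + 0.139 * (np.cos(ang) * e1 + np.sin(ang) * e2)
        atoms.append(make_atom(serial, name, "TYR", res_id, chain_id))
        coords.append(pos)
        serial += 1
    cz = centroid - 0.139 * e1  # para position (CZ is ring_names[3], at angle pi)
    atoms.append(make_atom(serial, "OH", "TYR", res_id, chain_id))
    coords.append(cz - 0.136 * e1)


def _append_arginine_side_chain(
    atoms: list[Atom], coords: list[np.ndarray], chain_id: str, res_id: int
) -> None:
    """Attach CB-CG-CD-NE-CZ-(NH1,NH2) guanidine group with hydrogens."""
    _rename_residue(atoms, chain_id, res_id, "ARG")
    ca, u, e1, e2 = _residue_frame(atoms, np.asarray(coords), chain_id, res_id)
    serial = max(a.serial for a in atoms) + 1
    positions = {
        "CB": ca + 0.153 * u,
        "CG": ca + 0.28 * u + 0.05 * e1,
        "CD": ca + 0.42 * u,
        "NE": ca + 0.55 * u + 0.05 * e1,
    }
    cz = ca + 0.68 * u
    positions["CZ"] = cz
    positions["NH1"] = cz + 0.133 * (np.cos(np.pi / 3) * u + np.sin(np.pi / 3) * e1)
    positions["NH2"] = cz + 0.133 * (np.cos(np.pi / 3) * u - np.sin(np.pi / 3) * e1)
    positions["HE"] = positions["NE"] + 0.101 * e2
    positions["HH11"] = positions["NH1"] + 0.101 * u
    positions["HH12"] = positions["NH1"] + 0.101 * e1
    positions["HH21"] = positions["NH2"] + 0.101 * u
    positions["HH22"] = positions["NH2"] - 0.101 * e1
    for name, pos in positions.items():
        atoms.append(make_atom(serial, name, "ARG", res_id, chain_id))
        coords.append(pos)
        serial += 1


def _append_isoleucine_side_chain(
    atoms: list[Atom], coords: list[np.ndarray], chain_id: str, res_id: int
) -> None:
    _rename_residue(atoms, chain_id, res_id, "ILE")
    ca, u, e1, e2 = _residue_frame(atoms, np.asarray(coords), chain_id, res_id)
    serial = max(a.serial for a in atoms) + 1
    for name, pos in (
        ("CB", ca + 0.153 * u),
        ("CG1", ca + 0.28 * u + 0.06 * e1),
        ("CG2", ca + 0.25 * u - 0.09 * e1),
        ("CD1", ca + 0.41 * u + 0.08 * e1),
    ):
        atoms.append(make_atom(serial, name, "ILE", res_id, chain_id))
        coords.append(pos)
        serial += 1


def make_receptor_body() -> Structure:
    """Synthetic 40-residue receptor (chain E, residues 130-169, Tyr151 ring)."""
    atoms, coords = _chain_body(RECEPTOR_CHAIN, 130, 40, 0.75, serial_start=1)
    _append_tyrosine_ring(atoms, coords, RECEPTOR_CHAIN, 151)
    _rename_residue(atoms, RECEPTOR_CHAIN, 141, "PHE")
    return Structure(atoms, Frame(np.asarray(coords)))


def make_ligand_body() -> Structure:
    """Synthetic 30-residue ligand (chain I, residues 1-30, Arg17 guanidine)."""
    atoms, coords = _chain_body(LIGAND_CHAIN, 1, 30, 0.65, serial_start=1001)
    _append_arginine_side_chain(atoms, coords, LIGAND_CHAIN, 17)
    _append_isoleucine_side_chain(atoms, coords, LIGAND_CHAIN, 19)
    _rename_residue(atoms, LIGAND_CHAIN, 14, "CYS")
    return Structure(atoms, Frame(np.asarray(coords)))


def template_reference_spec() -> ReferencePointSpec:
    """Reference-point selections matching the synthetic template's numbering."""
    return ReferencePointSpec(
        T1=SelectionSpec(RECEPTOR_CHAIN, None, "backbone"),
        T2=SelectionSpec(RECEPTOR_CHAIN, (150, 158), "backbone"),
        T3=SelectionSpec(RECEPTOR_CHAIN, (133, 140), "backbone"),
        B1=SelectionSpec(LIGAND_CHAIN, None, "backbone"),
        B2=SelectionSpec(LIGAND_CHAIN, (20, 26), "backbone"),
        B3=SelectionSpec(LIGAND_CHAIN, (14, 16), "backbone"),
    )


# --------------------------------------------------------------------------
# Rigid-body placement with exact positional coordinates
# --------------------------------------------------------------------------


def _nerf(p3: np.ndarray, p2: np.ndarray, p1: np.ndarray, r: float, theta: float, phi: float) -> np.ndarray:
    """Place X so |X-p1| = r, angle(p2,p1,X) = theta, dihedral(p3,p2,p1,X) = phi."""
    bc = p1 - p2
    bc = bc / np.linalg.norm(bc)
    ab = p2 - p3
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-r * np.cos(theta), r * np.sin(theta) * np.cos(phi), -r * np.sin(theta) * np.sin(phi)]
    )
    return p1 + d[0] * bc + d[1] * m + d[2] * n


def _b1_frame(t1: np.ndarray, t2: np.ndarray, b1: np.ndarray) -> np.ndarray:
    """Orthonormal frame (columns) at B1 tied to the receptor reference points."""
    u = b1 - t1
    u = u / np.linalg.norm(u)
    t = t2 - t1
    v = t - np.dot(t, u) * u
    v = v / np.linalg.norm(v)
    w = np.cross(u, v)
    return np.column_stack([u, v, w])


@dataclass
class _PlacementEngine:
    """Places the template ligand at target (r, theta_p, phi_p) poses.

    The ligand's internal orientation is stored relative to a local frame
    tied to the B1-T1 axis, so at zero jitter the orientational coordinates
    (theta_o, phi_o, psi_o) are exactly constant across placements.
    """

    receptor: Structure
    ligand: Structure
    spec: ReferencePointSpec

    def __post_init__(self) -> None:
        top = self.receptor.topology
        rc = self.receptor.coordinates
        self._t1 = self._com(top, rc, self.spec.T1)
        self._t2 = self._com(top, rc, self.spec.T2)
        self._t3 = self._com(top, rc, self.spec.T3)
        lig_b1_idx = select_atoms(self.ligand.topology, self.spec.B1)
        lig_masses = masses_of(self.ligand.topology)
        b1_local = center_of_mass(self.ligand.coordinates[lig_b1_idx], lig_masses[lig_b1_idx])
        # canonical pose: bound-state geometry, identity internal orientation
        x0 = _nerf(self._t3, self._t2, self._t1, BOUND_R, BOUND_THETA_P, BOUND_PHI_P)
        f0 = _b1_frame(self._t1, self._t2, x0)
        self._local = (self.ligand.coordinates - b1_local) @ f0  # rows: F0^T (x - b1)

    @staticmethod
    def _com(topology, coords, sel):
        idx = select_atoms(list(topology), sel)
        return center_of_mass(coords[idx], masses_of(topology)[idx])

    def place(
        self,
        r: float,
        theta_p: float,
        phi_p: float,
        jitter: Rotation | None = None,
    ) -> np.ndarray:
        """Ligand coordinates for the target pose (optionally jittered about B1)."""
        x = _nerf(self._t3, self._t2, self._t1, r, theta_p, phi_p)
        f = _b1_frame(self._t1, self._t2, x)
        offsets = self._local @ f.T
        if jitter is not None:
            offsets = jitter.apply(offsets)
        return x + offsets


def make_template_complex() -> Structure:
    """Synthetic two-chain complex in the fully bound pose (r = 2.65 nm).

    This is the packaged stand-in for a prepared crystal-structure complex:
    a geometric construction, not experimental data.
    """
    receptor = make_receptor_body()
    ligand = make_ligand_body()
    engine = _PlacementEngine(receptor, ligand, template_reference_spec())
    lig_coords = engine.place(BOUND_R, BOUND_THETA_P, BOUND_PHI_P)
    topology = receptor.topology + ligand.topology
    coords = np.vstack([receptor.coordinates, lig_coords])
    return Structure(topology, Frame(coords))


# Backwards-friendly alias used by the acceptance pipeline.
make_synthetic_complex = make_template_complex


# --------------------------------------------------------------------------
# Two-state trajectory generator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StatePlan:
    """Planned Gaussian distributions of the positional coordinates in one state."""

    name: str
    n_frames: int
    r_mean: float
    r_sd: float
    theta_p_mean: float = BOUND_THETA_P
    theta_p_sd: float = 0.03
    phi_p_mean: float = BOUND_PHI_P
    phi_p_sd: float = 0.03
    jitter_sd: float = 0.02  # rad, SD of the random rotation angle about B1

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        for sd in (self.r_sd, self.theta_p_sd, self.phi_p_sd):
            if sd < 0:
                raise ValueError("spreads must be non-negative")


@dataclass(frozen=True)
class TogglePlan:
    """Which planted interface interactions are 'on' in which states.

    The defaults mirror the study system's interface logic: the arginine
    side-chain hydrogen bond to a receptor backbone carbonyl and the
    heavy-atom contact exist in the fully bound state and are broken in the
    prebound state, while the cation-pi contact (guanidine CZ near the
    tyrosine ring centroid) appears only in the prebound state.
    """

    hbond_on: tuple[str, ...] = ("bound",)
    contact_on: tuple[str, ...] = ("bound",)
    cation_pi_on: tuple[str, ...] = ("prebound",)
    hbond_r_da: float = 0.29
    hbond_off_r_da: float = 0.50
    contact_distance: float = 0.30
    contact_off_distance: float = 0.60
    cation_pi_distance: float = 0.40


@dataclass(frozen=True)
class TwoStateTrajectoryPlan:
    states: tuple[StatePlan, ...]
    toggles: TogglePlan = TogglePlan()
    stride_ps: float = 10.0
    seed: int = 0

    @classmethod
    def defaults(cls, n_frames_per_state: int = 200, seed: int = 0) -> "TwoStateTrajectoryPlan":
        """Bound/prebound plan with the study system's r distributions."""
        return cls(
            states=(
                StatePlan("bound", n_frames_per_state, 2.65, 0.04),
                StatePlan(
                    "prebound",
                    n_frames_per_state,
                    2.85,
                    0.05,
                    theta_p_mean=BOUND_THETA_P + 0.2,
                    phi_p_mean=BOUND_PHI_P + 0.2,
                ),
            ),
            seed=seed,
        )


@dataclass
class TwoStateGroundTruth:
    """Per-frame planted values returned next to the generated trajectory."""

    labels: np.ndarray  # state name per frame
    r: np.ndarray
    theta_p: np.ndarray
    phi_p: np.ndarray
    hbond_on: np.ndarray  # bool per frame
    contact_on: np.ndarray
    cation_pi_on: np.ndarray
    state_counts: dict[str, int] = field(default_factory=dict)


#: Atom roles the generator plants interactions on (template naming).
PLANTED_HBOND = {
    "donor": (LIGAND_CHAIN, 17, "NH1"),
    "hydrogen": (LIGAND_CHAIN, 17, "HH11"),
    "acceptor": (RECEPTOR_CHAIN, 141, "O"),
}
PLANTED_CONTACT = {
    "ligand_atom": (LIGAND_CHAIN, 19, "CD1"),
    "receptor_atom": (RECEPTOR_CHAIN, 140, "O"),
}
PLANTED_CATION_PI = {
    "arginine": (LIGAND_CHAIN, 17),
    "tyrosine": (RECEPTOR_CHAIN, 151),
}


def _atom_index(topology: Sequence[Atom], chain: str, res_id: int, name: str) -> int:
    for i, a in enumerate(topology):
        if a.chain_id == chain and a.residue_index == res_id and a.name == name:
            return i
    raise StructureError(f"atom {chain}/{res_id}/{name} not in topology")


def _place_guanidine(
    coords: np.ndarray,
    index_of: Callable[[str], int],
    cz: np.ndarray,
    axis: np.ndarray,
    side: np.ndarray,
) -> None:
    """Write a rigid guanidine group (CZ + NE/NH1/NH2 + H's) into *coords*.

    *axis* points from CZ toward NH1 (the "business" nitrogen); *side* is a
    perpendicular in-plane direction.
    """
    coords[index_of("CZ")] = cz
    nh1 = cz + 0.133 * axis
    ne = cz + 0.133 * (np.cos(2 * np.pi / 3) * axis + np.sin(2 * np.pi / 3) * side)
    nh2 = cz + 0.133 * (np.cos(2 * np.pi / 3) * axis - np.sin(2 * np.pi / 3) * side)
    coords[index_of("NH1")] = nh1
    coords[index_of("NE")] = ne
    coords[index_of("NH2")] = nh2
    coords[index_of("HH11")] = nh1 + 0.101 * axis
    coords[index_of("HH12")] = nh1 + 0.101 * side
    coords[index_of("HE")] = ne + 0.101 * (ne - cz) / np.linalg.norm(ne - cz)
    coords[index_of("HH21")] = nh2 + 0.101 * (nh2 - cz) / np.linalg.norm(nh2 - cz)
    coords[index_of("HH22")] = nh2 - 0.101 * side


def generate_two_state_trajectory(
    plan: TwoStateTrajectoryPlan,
) -> tuple[Trajectory, TwoStateGroundTruth]:
    """Generate a rigid-body two-state trajectory plus its ground truth.

    Placement solves for the ligand pose matching the drawn (r, theta_p,
    phi_p) exactly, then applies the orientational jitter — position before
    orientation.  Designated side-chain atoms are then displaced to toggle
    the planted hydrogen bond / contact / cation-pi interaction per state.
    """
    rng = np.random.default_rng(plan.seed)
    receptor = make_receptor_body()
    ligand = make_ligand_body()
    spec = template_reference_spec()
    engine = _PlacementEngine(receptor, ligand, spec)
    topology = receptor.topology + ligand.topology
    n_rec = receptor.n_atoms

    # pre-resolved planted-atom indices (full-complex numbering)
    def full_index(chain, res, name):
        return _atom_index(topology, chain, res, name)

    acc_idx = full_index(*PLANTED_HBOND["acceptor"])
    acceptor_pos = receptor.coordinates[acc_idx]
    contact_rec_idx = full_index(*PLANTED_CONTACT["receptor_atom"])
    contact_rec_pos = receptor.coordinates[contact_rec_idx]
    contact_lig_idx = full_index(*PLANTED_CONTACT["ligand_atom"])

    ring_chain, ring_res = PLANTED_CATION_PI["tyrosine"]
    ring_idx = [
        full_index(ring_chain, ring_res, n) for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    ]
    ring_centroid = receptor.coordinates[ring_idx].mean(axis=0)
    ring_a = receptor.coordinates[full_index(ring_chain, ring_res, "CG")] - ring_centroid
    ring_b = receptor.coordinates[full_index(ring_chain, ring_res, "CE1")] - ring_centroid
    ring_normal = np.cross(ring_a, ring_b)
    ring_normal /= np.linalg.norm(ring_normal)
    # orient the normal away from the receptor centre so the planted guanidine
    # sits on the solvent side of the ring
    if np.dot(ring_normal, ring_centroid - receptor.coordinates.mean(axis=0)) < 0:
        ring_normal = -ring_normal

    arg_chain, arg_res = PLANTED_CATION_PI["arginine"]
    guanidine_names = ("CZ", "NE", "NH1", "NH2", "HE", "HH11", "HH12", "HH21", "HH22")
    guanidine_idx = {n: full_index(arg_chain, arg_res, n) for n in guanidine_names}

    heavy_rec = np.array([i for i, a in enumerate(receptor.topology) if not a.is_hydrogen])
    heavy_lig = np.array([i for i, a in enumerate(ligand.topology) if not a.is_hydrogen])

    frames: list[Frame] = []
    labels, r_truth, th_truth, ph_truth = [], [], [], []
    hbond_truth, contact_truth, pi_truth = [], [], []
    t = 0.0
    for state in plan.states:
        for _ in range(state.n_frames):
            r = rng.normal(state.r_mean, state.r_sd)
            theta = rng.normal(state.theta_p_mean, state.theta_p_sd)
            phi = rng.normal(state.phi_p_mean, state.phi_p_sd)
            jitter = None
            if state.jitter_sd > 0:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                jitter = Rotation.from_rotvec(rng.normal(0.0, state.jitter_sd) * axis)
            lig_coords = engine.place(r, theta, phi, jitter)

            # clash guard on the rigid bodies (before side-chain overrides)
            min_gap = cdist(receptor.coordinates[heavy_rec], lig_coords[heavy_lig]).min()
            if min_gap < 0.12:
                raise StructureError(
                    f"infeasible geometry: inter-chain clash ({min_gap:.3f} nm) at r={r:.3f}"
                )

            coords = np.vstack([receptor.coordinates, lig_coords])

            hb_on = state.name in plan.toggles.hbond_on
            ct_on = state.name in plan.toggles.contact_on
            pi_on = state.name in plan.toggles.cation_pi_on

            def gidx(name):
                return guanidine_idx[name]

            if pi_on:
                cz = ring_centroid + plan.toggles.cation_pi_distance * ring_normal
                side = ring_a / np.linalg.norm(ring_a)
                axis = np.cross(ring_normal, side)
                _place_guanidine(coords, gidx, cz, axis, side)
            elif hb_on:
                # donor nitrogen at r_DA from the acceptor, H on the N-A line
                d = coords[n_rec:].mean(axis=0) - acceptor_pos
                d /= np.linalg.norm(d)
                nh1 = acceptor_pos + plan.toggles.hbond_r_da * d
                cz = nh1 + 0.133 * d
                side = np.cross(d, [0.0, 0.0, 1.0])
                side /= np.linalg.norm(side)
                _place_guanidine(coords, gidx, cz, -d, side)
                coords[gidx("HH11")] = nh1 - 0.101 * d  # delta_HDA = 0
            else:
                # park the guanidine off both partners, toward the ligand body
                d = coords[n_rec:].mean(axis=0) - acceptor_pos
                d /= np.linalg.norm(d)
                cz = acceptor_pos + plan.toggles.hbond_off_r_da * d + 0.133 * d
                side = np.cross(d, [0.0, 0.0, 1.0])
                side /= np.linalg.norm(side)
                _place_guanidine(coords, gidx, cz, -d, side)

            dist = plan.toggles.contact_distance if ct_on else plan.toggles.contact_off_distance
            direction = coords[n_rec:].mean(axis=0) - contact_rec_pos
            direction /= np.linalg.norm(direction)
            coords[contact_lig_idx] = contact_rec_pos + dist * direction

            frames.append(Frame(coords, time=t))
            t += plan.stride_ps
            labels.append(state.name)
            r_truth.append(r)
            th_truth.append(theta)
            ph_truth.append(phi)
            hbond_truth.append(hb_on)
            contact_truth.append(ct_on)
            pi_truth.append(pi_on)

    truth = TwoStateGroundTruth(
        labels=np.array(labels),
        r=np.array(r_truth),
        theta_p=np.array(th_truth),
        phi_p=np.array(ph_truth),
        hbond_on=np.array(hbond_truth),
        contact_on=np.array(contact_truth),
        cation_pi_on=np.array(pi_truth),
        state_counts={s.name: s.n_frames for s in plan.states},
    )
    return Trajectory(topology, frames), truth


# --------------------------------------------------------------------------
# Umbrella-window sampler (exact inverse-CDF on a fine grid)
# --------------------------------------------------------------------------


def generate_umbrella_samples(
    potential: Callable[[np.ndarray], np.ndarray],
    centers: Sequence[float],
    force_constant: float,
    n_per_window: int,
    seed: int,
    temperature: float = 300.0,
    support: tuple[float, float] | None = None,
    grid_points: int = 4001,
    stride_ps: float = 10.0,
):
    """Draw exact samples from each window's biased Boltzmann distribution.

    ``p_k(xi) ∝ exp(-(U(xi) + k/2 (xi - xi_k)^2) / kT)`` is evaluated on a
    fine grid and sampled by inverse-CDF interpolation, so the samples are
    iid draws from the true biased density (no MD autocorrelation).
    Returns a :class:`prebound.wham.WindowSet`.
    """
    from .wham import KB_KJ_PER_MOL_K, UmbrellaWindow, WindowSet

    centers = np.asarray(centers, dtype=float)
    if support is None:
        margin = 4.0 * np.sqrt(KB_KJ_PER_MOL_K * temperature / force_constant) + 0.05
        support = (centers.min() - margin, centers.max() + margin)
    grid = np.linspace(support[0], support[1], grid_points)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.asarray(potential(grid), dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("potential is non-finite on the sampling range")
    kt = KB_KJ_PER_MOL_K * temperature
    rng = np.random.default_rng(seed)
    windows = []
    for xi_k in centers:
        energy = u + 0.5 * force_constant * (grid - xi_k) ** 2
        log_p = -(energy - energy.min()) / kt
        p = np.exp(log_p)
        cdf = np.cumsum(p)
        cdf /= cdf[-1]
        samples = np.interp(rng.random(n_per_window), cdf, grid)
        times = np.arange(n_per_window) * stride_ps
        windows.append(UmbrellaWindow(center=xi_k, force_constant=force_constant,
                                      samples=samples, times=times))
    return WindowSet(windows=windows, temperature=temperature)


# --------------------------------------------------------------------------
# Dwell-series generator (piecewise Ornstein-Uhlenbeck)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DwellSegment:
    state: str  # "bound" | "prebound" | "dissociated"
    duration_ns: float
    level_nm: float
    noise_sd_nm: float

    def __post_init__(self) -> None:
        if self.duration_ns <= 0:
            raise ValueError("segment duration must be positive")
        if self.noise_sd_nm < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass(frozen=True)
class DwellPlan:
    segments: tuple[DwellSegment, ...]
    stride_ps: float = 2.0
    seed: int = 0
    tau_ps: float = 20.0  # OU relaxation time


@dataclass
class DwellSeries:
    times: np.ndarray  # ps
    r: np.ndarray  # nm
    true_intervals: list[tuple[float, float]]  # prebound (start, end) in ps
    labels: np.ndarray


def generate_dwell_series(plan: DwellPlan) -> DwellSeries:
    """Piecewise OU process around each segment's level, with ground truth.

    With zero noise the series equals the planned step function exactly.
    """
    rng = np.random.default_rng(plan.seed)
    dt = plan.stride_ps
    decay = np.exp(-dt / plan.tau_ps)
    r_values, labels = [], []
    intervals = []
    t = 0.0
    for seg in plan.segments:
        n = int(round(seg.duration_ns * 1000.0 / dt))
        start_t = t
        kick = seg.noise_sd_nm * np.sqrt(1.0 - decay**2)
        noise = rng.normal(size=n)
        # each segment starts at its own level (a state jump), with the OU
        # initialised from the stationary distribution
        x = seg.level_nm + seg.noise_sd_nm * rng.normal()
        for i in range(n):
            x = seg.level_nm + (x - seg.level_nm) * decay + kick * noise[i]
            r_values.append(x)
            labels.append(seg.state)
            t += dt
        if seg.state == "prebound":
            intervals.append((start_t, t - dt))
    times = np.arange(len(r_values)) * dt
    return DwellSeries(times=times, r=np.array(r_values), true_intervals=intervals,
                       labels=np.array(labels))
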