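import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from prebound import interaction_analysis as ia
from prebound.collective_variables import compute_cv_series
from prebound.structure_io import Frame, Structure, Trajectory, make_atom


def build_structure(entries):
    """entries: (name, resname, resid, chain, xyz)."""
    atoms = [
        make_atom(i + 1, name, resname, resid, chain)
        for i, (name, resname, resid, chain, _) in enumerate(entries)
    ]
    coords = np.array([e[4] for e in entries], dtype=float)
    return Structure(atoms, Frame(coords))


def two_atom_structure(distance):
    return build_structure(
        [
            ("CA", "ALA", 1, "A", (0.0, 0.0, 0.0)),
            ("CA", "ALA", 1, "B", (distance, 0.0, 0.0)),
        ]
    )


class TestContacts:
    @pytest.mark.parametrize("distance,expected", [(0.34, True), (0.36, False), (0.35, False)])
    def test_strict_cutoff(self, distance, expected):
        s = two_atom_structure(distance)
        definition = ia.ContactDefinition(partner_a=[0], partner_b=[1])
        present, dmin = ia.contact_present(s, definition)
        assert present is expected
        assert dmin == pytest.approx(distance)

    def test_min_distance_matches_brute_force(self, rng):
        for _ in range(20):
            xa = rng.normal(size=(6, 3))
            xb = rng.normal(size=(4, 3)) + 1.0
            entries = [("CA", "ALA", 1, "A", tuple(x)) for x in xa] + [
                ("CA", "ALA", 1, "B", tuple(x)) for x in xb
            ]
            s = build_structure(entries)
            _, dmin = ia.contact_present(
                s, ia.ContactDefinition(partner_a=list(range(6)), partner_b=list(range(6, 10)))
            )
            brute = min(
                np.linalg.norm(a - b) for a in xa for b in xb
            )
            assert dmin == pytest.approx(brute, abs=1e-12)

    def test_hydrogens_ignored(self):
        s = build_structure(
            [
                ("CA", "ALA", 1, "A", (0.0, 0.0, 0.0)),
                ("H", "ALA", 1, "B", (0.2, 0.0, 0.0)),  # would be a contact if counted
                ("CA", "ALA", 1, "B", (0.9, 0.0, 0.0)),
            ]
        )
        present, dmin = ia.contact_present(
            s, ia.ContactDefinition(partner_a=[0], partner_b=[1, 2])
        )
        assert not present and dmin == pytest.approx(0.9)


class TestContactHistogram:
    def make_trajectory(self, distances):
        frames = []
        topology = two_atom_structure(0.3).topology
        for i, d in enumerate(distances):
            coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
            frames.append(Frame(coords, time=2.0 * i))
        return Trajectory(topology, frames)

    def r_series(self, traj):
        from prebound.collective_variables import CVSeries

        r = np.array([f.coordinates[1, 0] for f in traj.frames])
        z = np.zeros_like(r)
        return CVSeries(times=traj.times, r=r, theta_p=z, phi_p=z, theta_o=z, phi_o=z, psi_o=z)

    def test_contact_only_below_threshold_r(self):
        distances = [0.30] * 5 + [0.60] * 5
        traj = self.make_trajectory(distances)
        series = self.r_series(traj)
        definition = ia.ContactDefinition(partner_a=[0], partner_b=[1], label="pair")
        df = ia.contact_histogram_along_r(traj, [definition], series, np.array([0.2, 0.45, 0.7]))
        low = df[(df.r_lo == 0.2)].frequency.item()
        high = df[(df.r_lo == 0.45)].frequency.item()
        assert low == 1.0 and high == 0.0

    def test_single_bin_gives_overall_fraction(self):
        distances = [0.30, 0.30, 0.60, 0.60]
        traj = self.make_trajectory(distances)
        df = ia.contact_histogram_along_r(
            traj,
            [ia.ContactDefinition(partner_a=[0], partner_b=[1])],
            self.r_series(traj),
            np.array([0.0, 1.0]),
        )
        assert df.frequency.item() == 0.5

    def test_empty_bins_flagged_not_zero_filled(self):
        traj = self.make_trajectory([0.30, 0.30])
        df = ia.contact_histogram_along_r(
            traj,
            [ia.ContactDefinition(partner_a=[0], partner_b=[1])],
            self.r_series(traj),
            np.array([0.0, 0.5, 1.0]),
        )
        empty = df[df.r_lo == 0.5]
        assert empty.n_frames.item() == 0 and np.isnan(empty.frequency.item())

    def test_frequencies_match_frame_by_frame_oracle(self, rng):
        distances = rng.uniform(0.25, 0.7, size=30)
        traj = self.make_trajectory(distances)
        definition = ia.ContactDefinition(partner_a=[0], partner_b=[1])
        edges = np.array([0.2, 0.45, 0.7001])
        df = ia.contact_histogram_along_r(traj, [definition], self.r_series(traj), edges)
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (distances >= lo) & (distances < hi)
            oracle = np.mean([d < 0.35 for d in distances[mask]])
            assert df[(df.r_lo == lo)].frequency.item() == pytest.approx(oracle)

    def test_misalignment_is_error(self):
        traj = self.make_trajectory([0.3, 0.3])
        series = self.r_series(self.make_trajectory([0.3, 0.3, 0.3]))
        with pytest.raises(ValueError, match="aligned"):
            ia.contact_histogram_along_r(
                traj, [ia.ContactDefinition(partner_a=[0], partner_b=[1])], series, np.array([0, 1.0])
            )


def hbond_probe(r_da, delta_deg):
    """Donor N + H + acceptor O at a prescribed (r_DA, delta_HDA)."""
    delta = np.radians(delta_deg)
    h = 0.10 * np.array([np.cos(delta), np.sin(delta), 0.0])
    return build_structure(
        [
            ("N", "ALA", 1, "A", (0.0, 0.0, 0.0)),
            ("H", "ALA", 1, "A", tuple(h)),
            ("O", "ALA", 2, "A", (r_da, 0.0, 0.0)),
        ]
    )


class TestWernetNilsson:
    @pytest.mark.parametrize(
        "r_da,delta,expected",
        [
            (0.30, 0.0, True),   # 0.30 < 0.33
            (0.33, 0.0, False),  # strict inequality at the apex
            (0.29, 30.0, True),  # threshold 0.33 - 0.00044*900 = 0.2904
            (0.2905, 30.0, False),
        ],
    )
    def test_formula_examples(self, r_da, delta, expected):
        records = ia.detect_hbonds(hbond_probe(r_da, delta))
        assert (len(records) == 1) is expected

    def test_decision_matches_direct_formula_on_grid(self):
        for r_da in np.linspace(0.20, 0.36, 9):
            for delta in np.linspace(0.0, 90.0, 10):
                detected = len(ia.detect_hbonds(hbond_probe(r_da, delta))) == 1
                formula = r_da < ia.wernet_nilsson_max_distance(delta)
                assert detected == formula, (r_da, delta)

    def test_reported_geometry(self):
        (rec,) = ia.detect_hbonds(hbond_probe(0.29, 20.0))
        assert rec.r_da_nm == pytest.approx(0.29)
        assert rec.delta_hda_deg == pytest.approx(20.0, abs=1e-9)

    def test_no_hydrogens_is_error(self):
        s = build_structure(
            [("N", "ALA", 1, "A", (0, 0, 0)), ("O", "ALA", 2, "A", (0.3, 0, 0))]
        )
        with pytest.raises(Exception, match="hydrogen"):
            ia.detect_hbonds(s)


class TestHBondFrequencies:
    def toggled_trajectory(self):
        on = hbond_probe(0.29, 0.0)
        # re-chain the acceptor so the bond is inter-chain
        entries_on = [
            ("N", "ALA", 1, "A", tuple(on.coordinates[0])),
            ("H", "ALA", 1, "A", tuple(on.coordinates[1])),
            ("O", "ALA", 2, "B", tuple(on.coordinates[2])),
        ]
        entries_off = [
            ("N", "ALA", 1, "A", (0.0, 0.0, 0.0)),
            ("H", "ALA", 1, "A", (0.10, 0.0, 0.0)),
            ("O", "ALA", 2, "B", (0.60, 0.0, 0.0)),
        ]
        s_on = build_structure(entries_on)
        s_off = build_structure(entries_off)
        frames = [
            Frame(s_on.coordinates if i % 2 == 0 else s_off.coordinates, time=float(i))
            for i in range(10)
        ]
        return Trajectory(s_on.topology, frames)

    def test_half_toggled_gives_half_frequency(self):
        table = ia.hbond_frequencies(self.toggled_trajectory(), "A", "B")
        assert table.frequencies.iloc[0] == pytest.approx(0.5)

    def test_intra_chain_bonds_excluded(self):
        s = hbond_probe(0.29, 0.0)  # all on chain A
        traj = Trajectory(s.topology, [Frame(s.coordinates, time=0.0)])
        table = ia.hbond_frequencies(traj, "A", "B")
        assert table.frequencies.empty

    def test_guanidine_donors_aggregate_by_or(self):
        """NE/NH1/NH2 donors share the R-s label: frequency is the frame-wise OR."""
        def arg_frame(which):
            # place the named N 0.29 nm from the acceptor, the others far away
            positions = {"NE": (2.0, 0, 0), "NH1": (2.0, 1.0, 0), "NH2": (2.0, -1.0, 0)}
            positions[which] = (0.29, 0.0, 0.0)
            entries = [("O", "GLY", 5, "B", (0.0, 0.0, 0.0))]
            for name, pos in positions.items():
                entries.append((name, "ARG", 17, "A", pos))
                hx = np.asarray(pos) - np.array([0.10, 0, 0]) if name == which else np.asarray(pos) + 0.1
                entries.append((f"H{name[1:]}1", "ARG", 17, "A", tuple(hx)))
            return build_structure(entries)

        frames_spec = ["NE", "NH1", "NH2", None]
        structures = [arg_frame(w) if w else arg_frame("NE") for w in frames_spec]
        # the None frame: move everything far so no bond at all
        far = structures[3].coordinates.copy()
        far[1:] += 5.0
        topo = structures[0].topology
        traj = Trajectory(
            topo, [Frame(s.coordinates if w else far, time=float(i)) for i, (s, w) in enumerate(zip(structures, frames_spec))]
        )
        table = ia.hbond_frequencies(traj, "A", "B")
        assert table.get("R17-s–G5-O") == pytest.approx(3 / 4)

    def test_report_threshold_filter(self):
        table = ia.hbond_frequencies(self.toggled_trajectory(), "A", "B", report_threshold=0.6)
        assert table.filtered().empty and not table.frequencies.empty


class TestGuanidineDistance:
    def arg_structure(self, ne, nh1, nh2, partner):
        return build_structure(
            [
                ("NE", "ARG", 17, "A", ne),
                ("NH1", "ARG", 17, "A", nh1),
                ("NH2", "ARG", 17, "A", nh2),
                ("O", "GLY", 5, "B", partner),
            ]
        )

    def test_equidistant_symmetry(self):
        root3_2 = np.sqrt(3) / 2
        s = self.arg_structure((1, 0, 0), (-0.5, root3_2, 0), (-0.5, -root3_2, 0), (0, 0, 2.0))
        d = ia.min_guanidine_distance(s, "A", 17, 3)
        assert d == pytest.approx(np.sqrt(1 + 4.0))

    def test_matches_three_way_min_oracle(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(4, 3))
            s = self.arg_structure(tuple(pts[0]), tuple(pts[1]), tuple(pts[2]), tuple(pts[3]))
            expected = min(np.linalg.norm(pts[i] - pts[3]) for i in range(3))
            assert ia.min_guanidine_distance(s, "A", 17, 3) == pytest.approx(expected)

    def test_non_arginine_is_error(self):
        s = build_structure(
            [("NE2", "GLN", 8, "A", (0, 0, 0)), ("O", "GLY", 5, "B", (1, 0, 0))]
        )
        with pytest.raises(Exception, match="ARG"):
            ia.min_guanidine_distance(s, "A", 8, 1)

    def test_missing_nitrogen_is_error(self):
        s = build_structure(
            [
                ("NE", "ARG", 17, "A", (0, 0, 0)),
                ("NH1", "ARG", 17, "A", (1, 0, 0)),
                ("O", "GLY", 5, "B", (2, 0, 0)),
            ]
        )
        with pytest.raises(Exception, match="NH2"):
            ia.min_guanidine_distance(s, "A", 17, 2)


class TestRingCentroid:
    def hexagon(self, target):
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        entries = []
        for k, name in enumerate(names):
            ang = k * np.pi / 3
            entries.append((name, "TYR", 151, "A", (0.139 * np.cos(ang), 0.139 * np.sin(ang), 0.0)))
        entries.append(("CZ", "ARG", 17, "B", target))
        return build_structure(entries)

    def test_target_at_center_is_zero(self):
        s = self.hexagon((0.0, 0.0, 0.0))
        assert ia.ring_centroid_distance(s, "A", 151, 6) == pytest.approx(0.0, abs=1e-12)

    def test_target_on_axis_at_height(self):
        s = self.hexagon((0.0, 0.0, 0.45))
        assert ia.ring_centroid_distance(s, "A", 151, 6) == pytest.approx(0.45)

    def test_incomplete_ring_is_error(self):
        s = build_structure(
            [
                ("CG", "TYR", 151, "A", (0, 0, 0)),
                ("CD1", "TYR", 151, "A", (1, 0, 0)),
                ("CZ", "ARG", 17, "B", (2, 0, 0)),
            ]
        )
        with pytest.raises(Exception, match="ring"):
            ia.ring_centroid_distance(s, "A", 151, 2)

    def test_prebound_frames_stay_below_cation_pi_cutoff(self, small_two_state):
        """Planted prebound geometry keeps the centroid-CZ distance < 0.45 nm."""
        traj, truth = small_two_state
        cz = next(
            i for i, a in enumerate(traj.topology)
            if a.chain_id == "I" and a.residue_index == 17 and a.name == "CZ"
        )
        for i in np.nonzero(truth.labels == "prebound")[0][:10]:
            assert ia.ring_centroid_distance(traj[int(i)], "E", 151, cz) < 0.45


class TestSASA:
    def test_isolated_atom_closed_form(self):
        s = build_structure([("O", "HOH", 1, "A", (0.0, 0.0, 0.0))])
        result = ia.sasa(s)
        exact = 4 * np.pi * (0.152 + 0.14) ** 2
        assert result.atom_areas_nm2[0] == pytest.approx(exact, rel=0.01)

    def test_fully_enclosed_atom_is_zero(self):
        from prebound.synthetic_data import _fibonacci_sphere

        entries = [("O", "HOH", 1, "A", (0.0, 0.0, 0.0))]
        for i, p in enumerate(_fibonacci_sphere(60, 0.25)):
            entries.append(("O", "HOH", i + 2, "A", tuple(p)))
        result = ia.sasa(build_structure(entries))
        assert result.atom_areas_nm2[0] == 0.0

    def test_symmetric_pair_has_equal_areas(self):
        s = build_structure(
            [("O", "HOH", 1, "A", (0.0, 0.0, 0.0)), ("O", "HOH", 2, "A", (0.2, 0.0, 0.0))]
        )
        result = ia.sasa(s)
        # the two atoms are mirror images; the discrete point set is not,
        # so equality holds to the point-discretisation error only
        assert result.atom_areas_nm2[0] == pytest.approx(result.atom_areas_nm2[1], rel=0.01)

    def test_translation_invariance_exact(self, rng):
        entries = [("O", "HOH", i + 1, "A", tuple(x)) for i, x in enumerate(rng.normal(scale=0.2, size=(5, 3)))]
        s = build_structure(entries)
        base = ia.sasa(s).atom_areas_nm2
        moved = Structure(s.topology, Frame(s.coordinates + np.array([1.0, -2.0, 3.0])))
        np.testing.assert_allclose(ia.sasa(moved).atom_areas_nm2, base, rtol=1e-12)

    def test_rotation_invariance_within_discretisation(self, rng):
        entries = [("O", "HOH", i + 1, "A", tuple(x)) for i, x in enumerate(rng.normal(scale=0.2, size=(5, 3)))]
        s = build_structure(entries)
        base = ia.sasa(s).atom_areas_nm2
        rot = Rotation.random(random_state=rng)
        moved = Structure(s.topology, Frame(rot.apply(s.coordinates)))
        np.testing.assert_allclose(ia.sasa(moved).atom_areas_nm2, base, rtol=0.02)

    def test_area_decreases_as_second_body_approaches(self):
        areas = []
        for d in [1.0, 0.5, 0.35, 0.25]:
            s = build_structure(
                [("O", "HOH", 1, "A", (0.0, 0.0, 0.0)), ("O", "HOH", 2, "A", (d, 0.0, 0.0))]
            )
            areas.append(ia.sasa(s).atom_areas_nm2[0])
        assert all(a >= b for a, b in zip(areas, areas[1:]))
        assert areas[-1] < areas[0]

    def test_residue_sums_equal_member_atoms(self, small_two_state):
        traj, _ = small_two_state
        structure = traj[0]
        result = ia.sasa(structure, n_sphere_points=120)
        total_by_residue = result.residue_areas.area_nm2.sum()
        assert total_by_residue == pytest.approx(result.atom_areas_nm2.sum(), rel=1e-9)
        area_17 = result.residue_area("I", 17)
        members = [
            i for i, a in enumerate(structure.topology)
            if a.chain_id == "I" and a.residue_index == 17
        ]
        assert area_17 == pytest.approx(result.atom_areas_nm2[members].sum(), rel=1e-9)
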