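"""Ring perception and the geometric interaction detectors."""

import numpy as np
import pytest

from ligmodes.fingerprints import (
    Fingerprint,
    InteractionCriteria,
    InteractionDetector,
    detect_hbond,
    detect_hydrophobic,
    detect_oh_pi,
    detect_pi_stacking,
    fingerprint_trajectory,
    perceive_rings,
    ring_geometry,
)
from ligmodes.structio import Trajectory
from ligmodes.synthdata import SyntheticComplexSpec, make_synthetic_trajectory

from helpers import (
    apply_rigid,
    benzene_atoms,
    hexagon_coords,
    mini_structure,
    phe_ring_atoms,
    random_rigid_motion,
)


class TestRingPerception:
    def test_pet_tetramer_has_four_rings(self, tetramer):
        rings = perceive_rings(tetramer, ["PTE"])
        assert len(rings) == 4
        assert [r.owner for r in rings] == [0, 1, 2, 3]
        assert all(len(r.atom_indices) == 6 for r in rings)

    def test_idealized_benzene(self):
        s = mini_structure(benzene_atoms(center=(1.0, 2.0, 3.0), normal=(0, 0, 1)))
        rings = perceive_rings(s, ["BNZ"])
        assert len(rings) == 1
        np.testing.assert_allclose(rings[0].centroid, [1.0, 2.0, 3.0], atol=1e-9)
        assert abs(rings[0].normal @ np.array([0, 0, 1.0])) == pytest.approx(1.0, abs=1e-9)

    def test_trp_two_rings_sharing_two_atoms(self):
        # fused indole: 5-ring and 6-ring sharing the CD2-CE2 edge
        hexa = hexagon_coords((0, 0, 0), (0, 0, 1), radius=1.39)
        six = dict(zip(("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"), hexa))
        edge_mid = (six["CD2"] + six["CE2"]) / 2
        out = edge_mid - np.array([0, 0, 0])  # radially outward from hexagon center
        out = out / np.linalg.norm(out)
        perp = np.cross([0, 0, 1.0], out)
        five = {
            "CG": edge_mid + 1.9 * out + 0.6 * perp,
            "CD1": edge_mid + 2.1 * out - 0.7 * perp,
            "NE1": edge_mid + 1.0 * out - 1.1 * perp,
        }
        atoms = [(n, "C", "TRP", 7, "A", tuple(p)) for n, p in six.items()]
        atoms += [(n, n[0], "TRP", 7, "A", tuple(p)) for n, p in five.items()]
        rings = perceive_rings(mini_structure(atoms), [])
        assert len(rings) == 2
        shared = set(rings[0].atom_indices) & set(rings[1].atom_indices)
        assert len(shared) == 2

    def test_incomplete_protein_ring_skipped(self):
        atoms = phe_ring_atoms((0, 0, 0), (0, 0, 1))[:-1]  # drop one ring atom
        rings = perceive_rings(mini_structure(atoms), [])
        assert rings == []

    def test_nonplanar_ligand_cycle_rejected(self):
        atoms = benzene_atoms((0, 0, 0), (0, 0, 1))
        bent = [
            (n, e, r, rs, c, (x, y, z + (1.0 if i == 0 else 0.0)), h)
            for i, (n, e, r, rs, c, (x, y, z), h) in enumerate(atoms)
        ]
        assert perceive_rings(mini_structure(bent), ["BNZ"]) == []


def _pocket_with_ligand(extra_protein_atoms, ligand_atoms):
    return mini_structure(list(extra_protein_atoms) + list(ligand_atoms))


class TestHydrophobic:
    def test_leucine_carbon_within_cutoff(self):
        s = _pocket_with_ligand(
            [("CD1", "C", "LEU", 9, "A", (4.0, 0, 0))],
            [("C1", "C", "LIG", 1, "L", (0, 0, 0), True)],
        )
        assert detect_hydrophobic(s.coords, s, ["LIG"]) == {("A", 9)}

    def test_far_contact_empty(self):
        s = _pocket_with_ligand(
            [("CD1", "C", "LEU", 9, "A", (6.0, 0, 0))],
            [("C1", "C", "LIG", 1, "L", (0, 0, 0), True)],
        )
        assert detect_hydrophobic(s.coords, s, ["LIG"]) == set()

    def test_planted_contact_set_matches_exhaustive_scan(self, two_mode_traj):
        traj, labels = two_mode_traj
        top = traj.topology
        frame = traj.coords[0]
        expected = set()
        lig_c = np.flatnonzero((top.resname == "PTE") & (top.element == "C"))
        prot_cs = np.flatnonzero(
            np.isin(top.element, ["C", "S"]) & (top.resname != "PTE") & ~top.is_hetero
        )
        for i in prot_cs:
            for j in lig_c:
                if np.linalg.norm(frame[i] - frame[j]) <= 4.5:
                    expected.add((str(top.chain_id[i]), int(top.resseq[i])))
        got = detect_hydrophobic(frame, top, ["PTE"])
        assert got == expected
        # and the planted ground truth: mode m touches its 8-residue window
        window = set(range(8 * labels[0] + 1, 8 * labels[0] + 9))
        assert {r for _, r in got} == window


class TestPiStacking:
    def _rings(self, centroid_d, angle_deg):
        prot = mini_structure(phe_ring_atoms((0, 0, 0), (0, 0, 1)))
        normal = (np.sin(np.deg2rad(angle_deg)), 0, np.cos(np.deg2rad(angle_deg)))
        lig = mini_structure(benzene_atoms((0, 0, centroid_d), normal))
        s = mini_structure(
            phe_ring_atoms((0, 0, 0), (0, 0, 1))
            + benzene_atoms((0, 0, centroid_d), normal)
        )
        rings = perceive_rings(s, ["BNZ"])
        prot_rings = [r for r in rings if isinstance(r.owner, tuple)]
        lig_rings = [r for r in rings if isinstance(r.owner, int)]
        return s, prot_rings, lig_rings

    def test_parallel_close_reported(self):
        s, pr, lr = self._rings(3.8, 0)
        assert detect_pi_stacking(s.coords, pr, lr) == {(("A", 10), 0)}

    def test_parallel_far_not_reported(self):
        s, pr, lr = self._rings(7.0, 0)
        assert detect_pi_stacking(s.coords, pr, lr) == set()

    def test_perpendicular_edge_to_face(self):
        s, pr, lr = self._rings(5.0, 90)
        assert detect_pi_stacking(s.coords, pr, lr) == {(("A", 10), 0)}

    def test_intermediate_angle_gap_not_reported(self):
        s, pr, lr = self._rings(5.0, 42)  # between the 35° and 50° windows
        assert detect_pi_stacking(s.coords, pr, lr) == set()


class TestHbond:
    def _ester_ligand(self, ser_og_distance):
        # methyl-ester fragment: C-O(keto) with bridging O and CH3
        lig = [
            ("C1", "C", "LIG", 1, "L", (0.0, 0.0, 0.0), True),
            ("O1", "O", "LIG", 1, "L", (0.0, 1.23, 0.0), True),   # carbonyl O
            ("O2", "O", "LIG", 1, "L", (1.34, 0.0, 0.0), True),   # bridging ester O
            ("C2", "C", "LIG", 1, "L", (2.77, 0.0, 0.0), True),
        ]
        prot = [
            ("CB", "C", "SER", 96, "A", (0.0, 1.23 + ser_og_distance, 1.5)),
            ("OG", "O", "SER", 96, "A", (0.0, 1.23 + ser_og_distance, 0.0)),
        ]
        return mini_structure(prot + lig)

    def test_serine_donor_to_carbonyl(self):
        s = self._ester_ligand(3.0)
        assert detect_hbond(s.coords, s, ["LIG"]) == {(("A", 96), "donor")}

    def test_beyond_cutoff_nothing(self):
        s = self._ester_ligand(4.0)
        assert detect_hbond(s.coords, s, ["LIG"]) == set()

    def test_ester_oxygens_are_acceptors_only(self):
        # backbone O (protein acceptor) near the ester O: no record, because
        # ester oxygens never act as donors
        s = mini_structure(
            [
                ("C", "C", "GLY", 5, "A", (1.34, 3.0, 1.2)),
                ("O", "O", "GLY", 5, "A", (1.34, 2.9, 0.0)),
                ("C1", "C", "LIG", 1, "L", (0.0, 0.0, 0.0), True),
                ("O1", "O", "LIG", 1, "L", (0.0, 1.23, 0.0), True),
                ("O2", "O", "LIG", 1, "L", (1.34, 0.0, 0.0), True),
                ("C2", "C", "LIG", 1, "L", (2.77, 0.0, 0.0), True),
            ]
        )
        assert detect_hbond(s.coords, s, ["LIG"]) == set()

    def test_hydroxyl_ligand_oxygen_donates_to_backbone(self):
        # terminal O on a carbon with no second oxygen: hydroxyl-like donor
        s = mini_structure(
            [
                ("C", "C", "GLY", 5, "A", (0.0, 4.1, 1.2)),
                ("O", "O", "GLY", 5, "A", (0.0, 4.13, 0.0)),
                ("C1", "C", "LIG", 1, "L", (0.0, 0.0, 0.0), True),
                ("O1", "O", "LIG", 1, "L", (0.0, 1.43, 0.0), True),
            ]
        )
        assert detect_hbond(s.coords, s, ["LIG"]) == {(("A", 5), "acceptor")}

    def test_single_planted_contact_matches_distance_scan(self):
        s = self._ester_ligand(2.9 - 1.23)  # OG exactly 2.9 Å above carbonyl O...
        got = detect_hbond(s.coords, s, ["LIG"])
        assert len(got) == 1 and got == {(("A", 96), "donor")}


class TestOHPi:
    def _probe(self, distance, in_plane=False):
        center = np.array([0.0, 0.0, 0.0])
        offset = np.array([distance, 0, 0]) if in_plane else np.array([0, 0, distance])
        atoms = benzene_atoms(center, (0, 0, 1)) + [
            ("OG1", "O", "THR", 91, "A", tuple(center + offset)),
            ("CB", "C", "THR", 91, "A", tuple(center + offset + np.array([0, 0, 1.4]))),
        ]
        return mini_structure(atoms)

    def test_axial_hydroxyl_at_ideal_distance(self):
        s = self._probe(3.5)
        assert detect_oh_pi(s.coords, s, ["BNZ"]) == {("A", 91)}

    def test_in_plane_hydroxyl_rejected(self):
        s = self._probe(3.5, in_plane=True)
        assert detect_oh_pi(s.coords, s, ["BNZ"]) == set()

    def test_far_hydroxyl_rejected(self):
        s = self._probe(6.0)
        assert detect_oh_pi(s.coords, s, ["BNZ"]) == set()


class TestFingerprintTrajectory:
    def test_static_pose_rows_identical(self, static_traj):
        traj, _ = static_traj
        fp = fingerprint_trajectory(traj, ["PTE"])
        assert fp.n_frames == traj.frame_count
        assert (fp.matrix == fp.matrix[0]).all()

    def test_two_modes_two_patterns(self, two_mode_traj):
        traj, labels = two_mode_traj
        fp = fingerprint_trajectory(traj, ["PTE"])
        patterns = {tuple(row) for row in fp.matrix}
        assert len(patterns) == 2

    def test_unbound_ligand_zero_columns(self):
        spec = SyntheticComplexSpec(n_modes=1, frames=3, jitter_sigma=0.0, seed=0)
        traj, _ = make_synthetic_trajectory(spec)
        coords = traj.coords.copy()
        lig = traj.topology.resname == "PTE"
        coords[:, lig] += np.array([0.0, -50.0, 0.0])
        moved = Trajectory(topology=traj.topology, coords=coords)
        fp = fingerprint_trajectory(moved, ["PTE"])
        assert fp.n_descriptors == 0

    def test_missing_ligand_is_error(self, static_traj):
        with pytest.raises(ValueError, match="not present"):
            fingerprint_trajectory(static_traj[0], ["XXX"])

    def test_concatenation_equals_row_concat(self, two_mode_traj):
        traj, _ = two_mode_traj
        half = traj.frame_count // 2
        part1 = Trajectory(topology=traj.topology, coords=traj.coords[:half])
        part2 = Trajectory(topology=traj.topology, coords=traj.coords[half:])
        fp1 = fingerprint_trajectory(part1, ["PTE"])
        fp2 = fingerprint_trajectory(part2, ["PTE"])
        fp_both = fingerprint_trajectory(traj, ["PTE"])
        combined = Fingerprint.concat([fp1, fp2])
        assert fp_both.labels == combined.labels
        assert (fp_both.matrix == combined.matrix).all()

    def test_csv_round_trip(self, tmp_path, two_mode_traj):
        fp = fingerprint_trajectory(two_mode_traj[0], ["PTE"])
        path = tmp_path / "fp.csv"
        fp.to_csv(path)
        back = Fingerprint.from_csv(path)
        assert back.labels == fp.labels
        assert (back.matrix == fp.matrix).all()


class TestDetectorProperties:
    def test_rigid_motion_invariance(self, two_mode_traj, rng):
        """All detectors are invariant under a global rigid motion."""
        traj, _ = two_mode_traj
        det = InteractionDetector(traj.topology, ["PTE"])
        frame = traj.coords[0]
        reference = det.descriptors_frame(frame)
        for _ in range(5):
            rot, t = random_rigid_motion(rng)
            assert det.descriptors_frame(apply_rigid(frame, rot, t)) == reference

    def test_atom_order_independence(self, rng):
        atoms = phe_ring_atoms((0, 0, 4.0), (0, 0, 1)) + benzene_atoms((0, 0, 0), (0, 0, 1))
        s = mini_structure(atoms)
        perm = rng.permutation(len(s))
        sp = s.subset(perm)
        rings_a = perceive_rings(s, ["BNZ"])
        rings_b = perceive_rings(sp, ["BNZ"])
        got_a = detect_pi_stacking(s.coords, [r for r in rings_a if isinstance(r.owner, tuple)], [r for r in rings_a if isinstance(r.owner, int)])
        got_b = detect_pi_stacking(sp.coords, [r for r in rings_b if isinstance(r.owner, tuple)], [r for r in rings_b if isinstance(r.owner, int)])
        assert got_a == got_b

    def test_threshold_monotonicity(self, two_mode_traj):
        """Enlarging distance thresholds never removes a detection."""
        traj, _ = two_mode_traj
        tight = InteractionCriteria()
        loose = InteractionCriteria(
            hydrophobic_d=6.0, pi_centroid_d_parallel=7.0, pi_centroid_d_tshaped=8.0,
            hbond_da_d=4.5, ohpi_d=6.0,
        )
        det_tight = InteractionDetector(traj.topology, ["PTE"], tight)
        det_loose = InteractionDetector(traj.topology, ["PTE"], loose)
        for f in range(0, traj.frame_count, 7):
            assert det_tight.descriptors_frame(traj.coords[f]) <= det_loose.descriptors_frame(
                traj.coords[f]
            )

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            InteractionCriteria(hydrophobic_d=-1.0)
        with pytest.raises(ValueError):
            InteractionCriteria(pi_angle_parallel=120.0)
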