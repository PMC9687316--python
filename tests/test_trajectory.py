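"""RMSD/RMSF trajectory metrics and geometric contact detection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from boomdock import synth
from boomdock.structio import Atom, Residue, Structure
from boomdock.trajectory import (Trajectory, hydrogen_bonds, hydrophobic_contacts,
                                 rmsd_series, rmsf_profile, select_chains)


def _two_chain_structure(offset=np.array([0.0, 20.0, 0.0])):
    a = synth.make_peptide_chain("AAAAAA", chain_id="A")
    b = synth.make_peptide_chain("AAA", chain_id="B")
    b = b.with_coords(b.coords() + offset)
    return Structure("cx", a.residues + b.residues)


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self):
        topo = synth.make_peptide_chain("AAAA")
        traj = Trajectory(topo, np.repeat(topo.coords()[None], 4, axis=0))
        series = rmsd_series(traj)
        np.testing.assert_allclose(series.values_nm, 0.0, atol=1e-12)

    def test_ligand_translation_captured_with_receptor_fit(self):
        s = _two_chain_structure()
        traj, _ = synth.make_trajectory(5, 0.0, structure=s,
                                        drift=("B", np.array([5.0, 0.0, 0.0])))
        series = rmsd_series(traj, 0, select_chains(["A"]), select_chains(["B"]))
        assert series.values_nm[0] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(series.values_nm[1:], 0.5, atol=1e-9)

    def test_self_fit_removes_rigid_motion(self):
        s = _two_chain_structure()
        traj, _ = synth.make_trajectory(5, 0.0, structure=s,
                                        drift=("B", np.array([5.0, 0.0, 0.0])))
        series = rmsd_series(traj, 0, select_chains(["B"]), select_chains(["B"]))
        np.testing.assert_allclose(series.values_nm, 0.0, atol=1e-9)

    def test_global_rigid_transform_invariance(self):
        rng = np.random.default_rng(6)
        traj, _ = synth.make_trajectory(6, 0.05, n_residues=4, seed=3)
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = Trajectory(traj.topology,
                           traj.frames @ rot.T + np.array([5.0, -3.0, 2.0]))
        ref = rmsd_series(traj).values_nm
        # transforming every frame AND the implicit frame-0 reference
        got = rmsd_series(moved).values_nm
        np.testing.assert_allclose(got, ref, atol=1e-9)

    def test_empty_selection_rejected(self):
        traj, _ = synth.make_trajectory(3, 0.0, n_residues=2)
        with pytest.raises(ValueError):
            rmsd_series(traj, 0, select_chains(["Z"]))


class TestRmsfProfile:
    def test_static_trajectory_is_zero(self):
        topo = synth.make_peptide_chain("AAA")
        traj = Trajectory(topo, np.repeat(topo.coords()[None], 3, axis=0))
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in rmsf_profile(traj).values_nm.values())

    def test_planted_sigma_recovered(self):
        traj, _ = synth.make_trajectory(2000, {("A", 5): 0.1}, n_residues=12, seed=2)
        prof = rmsf_profile(traj)
        assert prof.values_nm[("A", 5)] == pytest.approx(0.1 * np.sqrt(3), rel=0.05)

    def test_high_mobility_segment_exceeds_threshold(self):
        sigma = {("A", n): 0.25 for n in range(4, 8)}
        traj, _ = synth.make_trajectory(500, sigma, n_residues=12, seed=8)
        prof = rmsf_profile(traj)
        flagged = {key for key, v in prof.values_nm.items() if v > 0.3}
        assert flagged == set(sigma)  # 0.25·sqrt(3) ≈ 0.43 nm > 0.3 nm

    def test_single_frame_rejected(self):
        topo = synth.make_peptide_chain("AA")
        traj = Trajectory(topo, topo.coords()[None])
        with pytest.raises(ValueError):
            rmsf_profile(traj)


def _residue(chain, number, name3, atom_specs, serial0=1):
    atoms = [Atom(serial0 + i, name, element, np.array(pos, dtype=float))
             for i, (name, element, pos) in enumerate(atom_specs)]
    return Residue(chain, number, "", name3, atoms)


class TestHydrogenBonds:
    def test_single_cross_chain_pair_at_2_9(self):
        donor = _residue("A", 1, "SER", [("CA", "C", (0, 0, 0)), ("OG", "O", (1.5, 0, 0))])
        acceptor = _residue("B", 1, "ALA", [("CA", "C", (6, 0, 0)), ("O", "O", (4.4, 0, 0))],
                            serial0=10)
        s = Structure("hb", [donor, acceptor])
        bonds = hydrogen_bonds(s, ["A"], ["B"])
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)
        assert bonds[0].donor_atom == "OG" and bonds[0].acceptor_atom == "O"

    def test_no_bonds_beyond_cutoff(self):
        s = _two_chain_structure(offset=np.array([0.0, 10.0, 0.0]))
        assert hydrogen_bonds(s, ["A"], ["B"], d_max=3.5) == []

    def test_zero_cutoff_gives_nothing(self):
        s = _two_chain_structure(offset=np.array([0.0, 3.0, 0.0]))
        assert hydrogen_bonds(s, ["A"], ["B"], d_max=0.0) == []

    def test_proline_backbone_nitrogen_not_a_donor(self):
        pro = _residue("A", 1, "PRO", [("N", "N", (0, 0, 0))])
        acc = _residue("B", 1, "ALA", [("O", "O", (2.8, 0, 0))], serial0=5)
        assert hydrogen_bonds(Structure("p", [pro, acc]), ["A"], ["B"]) == []


class TestHydrophobicContacts:
    def test_cb_pair_at_3_8_is_side_chain_contact(self):
        r1 = _residue("A", 1, "ALA", [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))])
        r2 = _residue("B", 1, "ALA", [("CA", "C", (6.8, 0, 0)), ("CB", "C", (5.3, 0, 0))],
                      serial0=10)
        contacts = hydrophobic_contacts(Structure("hc", [r1, r2]), ["A"], ["B"])
        assert len(contacts) == 1
        c = contacts[0]
        assert c.distance == pytest.approx(3.8)
        assert c.receptor_chain_part == c.ligand_chain_part == "side"
        assert {c.receptor_atom, c.ligand_atom} == {"CB"}

    def test_polar_only_interface_is_empty(self):
        r1 = _residue("A", 1, "SER", [("OG", "O", (0, 0, 0))])
        r2 = _residue("B", 1, "SER", [("OG", "O", (3.0, 0, 0))], serial0=5)
        assert hydrophobic_contacts(Structure("p", [r1, r2]), ["A"], ["B"]) == []

    def test_matches_brute_force_all_pairs_scan(self, toy_complex):
        s, _ = toy_complex
        contacts = hydrophobic_contacts(s, ["R"], ["L"], d_max=6.0)
        got = sorted((c.receptor_residue, c.receptor_atom,
                      c.ligand_residue, c.ligand_atom) for c in contacts)
        expected = []
        for r in s.chain("R"):
            for l in s.chain("L"):
                for ar in r.atoms:
                    for al in l.atoms:
                        if ar.element == "C" and al.element == "C" and \
                                np.linalg.norm(ar.coords - al.coords) <= 6.0:
                            expected.append(((r.chain_id, r.number), ar.name,
                                             (l.chain_id, l.number), al.name))
        assert got == sorted(expected) and got  # non-trivial scan

    def test_symmetric_under_role_swap(self, toy_complex):
        s, _ = toy_complex
        fwd = hydrophobic_contacts(s, ["R"], ["L"])
        rev = hydrophobic_contacts(s, ["L"], ["R"])
        assert sorted((c.receptor_residue, c.ligand_residue, round(c.distance, 6))
                      for c in fwd) == \
            sorted((c.ligand_residue, c.receptor_residue, round(c.distance, 6))
                   for c in rev)

    def test_main_chain_annotation(self):
        r1 = _residue("A", 1, "GLY", [("CA", "C", (0, 0, 0))])
        r2 = _residue("B", 1, "GLY", [("CA", "C", (3.5, 0, 0))], serial0=5)
        (c,) = hydrophobic_contacts(Structure("mc", [r1, r2]), ["A"], ["B"])
        assert c.receptor_chain_part == c.ligand_chain_part == "main"
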