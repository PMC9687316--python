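"""SASA, ΔSASA interface detection, contacts and the affinity model."""

import math

import numpy as np
import pytest

from boomdock import synth
from boomdock.interface import (AffinityModel, ContactTable, GAS_CONSTANT,
                                RadiusSet, ResidueClassScheme, binding_affinity,
                                class_pair_key, delta_sasa, dg_from_kd,
                                interfacial_contacts, kd_from_dg, sasa)
from boomdock.structio import Atom, Residue, Structure


def _atom_structure(positions, elements):
    atoms = [Atom(i + 1, e, e, p) for i, (p, e) in enumerate(zip(positions, elements))]
    return Structure("atoms", [Residue("A", 1, "", "ALA", atoms)])


def _two_sphere_area(r_expanded: float, d: float) -> float:
    """Closed-form joint accessible area of two equal spheres at distance d."""
    if d >= 2 * r_expanded:
        return 2 * 4 * math.pi * r_expanded ** 2
    h = r_expanded - d / 2
    return 2 * (4 * math.pi * r_expanded ** 2 - 2 * math.pi * r_expanded * h)


RS = RadiusSet.default()


class TestSasa:
    def test_isolated_atom_matches_sphere_area(self):
        s = _atom_structure([[0.0, 0.0, 0.0]], ["C"])
        area = sasa(s, RS, 960).total()
        assert area == pytest.approx(4 * math.pi * 3.1 ** 2, rel=0.01)

    def test_fully_enclosed_atom_has_zero_area(self):
        rng = np.random.default_rng(2)
        shell = [1.8 * u / np.linalg.norm(u)
                 for u in rng.normal(size=(40, 3))]
        s = _atom_structure([[0.0, 0.0, 0.0]] + shell, ["C"] * 41)
        assert sasa(s, RS, 960).atom_areas[0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.0, 5.0, 6.0])
    def test_two_sphere_closed_form(self, d):
        s = _atom_structure([[0.0, 0.0, 0.0], [d, 0.0, 0.0]], ["C", "C"])
        area = sasa(s, RS, 960).total()
        assert area == pytest.approx(_two_sphere_area(3.1, d), rel=0.01)

    def test_convergence_under_point_doubling(self):
        s = _atom_structure([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]], ["C", "C"])
        a480 = sasa(s, RS, 480).total()
        a960 = sasa(s, RS, 960).total()
        assert abs(a960 - a480) / a960 < 0.005

    def test_separated_chains_are_additive(self, toy_complex):
        structure, _ = toy_complex
        rec = structure.subset_chains(["R"])
        lig = structure.subset_chains(["L"])
        # move the ligand far away so no cross-chain burial remains
        far = Structure("far", rec.residues
                        + lig.with_coords(lig.coords() + np.array([0, 500.0, 0])).residues)
        joint = sasa(far, RS, 240)
        alone = np.concatenate([sasa(rec, RS, 240).atom_areas,
                                sasa(lig, RS, 240).atom_areas])
        np.testing.assert_allclose(joint.atom_areas, alone, atol=1e-6)

    def test_unknown_element_names_atom(self):
        s = _atom_structure([[0.0, 0.0, 0.0]], ["XX"])
        with pytest.raises(KeyError, match="XX"):
            sasa(s, RS, 60)


class TestDeltaSasa:
    def test_far_apart_chains_have_empty_interface(self):
        a = synth.make_peptide_chain("AAAA", chain_id="A")
        b = synth.make_peptide_chain("AAAA", chain_id="B")
        b = b.with_coords(b.coords() + np.array([0.0, 50.0, 0.0]))
        s = Structure("apart", a.residues + b.residues)
        profile = delta_sasa(s, ["A"], ["B"], RS, n_points=240)
        assert profile.interface == set()
        assert all(abs(v) < 1e-9 for v in profile.delta.values())

    def test_single_planted_contact_pair_detected_exactly(self):
        s, truth = synth.make_toy_complex(6, 6, [(3, 4)])
        profile = delta_sasa(s, ["R"], ["L"], RS, n_points=240)
        assert profile.interface == {("R", 3), ("L", 4)}
        assert all(v >= -1e-6 for v in profile.delta.values())

    def test_overlapping_chain_sets_rejected(self, toy_complex):
        s, _ = toy_complex
        with pytest.raises(ValueError):
            delta_sasa(s, ["R"], ["R", "L"], RS, n_points=60)


class TestInterfacialContacts:
    def test_separated_chains_have_no_contacts(self):
        a = synth.make_peptide_chain("AAA", chain_id="A")
        b = synth.make_peptide_chain("AAA", chain_id="B")
        b = b.with_coords(b.coords() + np.array([0.0, 40.0, 0.0]))
        table = interfacial_contacts(Structure("apart", a.residues + b.residues),
                                     ["A"], ["B"])
        assert table.total == 0

    def test_planted_pairs_match_brute_force_scan(self, toy_complex):
        s, truth = toy_complex
        table = interfacial_contacts(s, ["R"], ["L"])
        got = sorted((r[1], l[1]) for r, l, _ in table.pairs)
        # O(n^2) all-pairs oracle over heavy atoms
        expected = []
        for r in s.chain("R"):
            for l in s.chain("L"):
                d = min(np.linalg.norm(ar.coords - al.coords)
                        for ar in r.atoms if ar.is_heavy
                        for al in l.atoms if al.is_heavy)
                if d <= 5.5:
                    expected.append((r.number, l.number))
        assert got == sorted(expected) == sorted(truth)

    def test_all_apolar_scheme_lands_in_aa(self, toy_complex):
        s, truth = toy_complex
        scheme = ResidueClassScheme(classes={aa: "apolar" for aa in "ACDEFGHIKLMNPQRSTVWY"})
        table = interfacial_contacts(s, ["R"], ["L"], scheme)
        assert table.counts["aa"] == table.total == len(truth)

    def test_symmetric_under_role_swap(self, toy_complex):
        s, _ = toy_complex
        t1 = interfacial_contacts(s, ["R"], ["L"])
        t2 = interfacial_contacts(s, ["L"], ["R"])
        assert t1.counts == t2.counts
        assert sorted((l, r) for r, l, _ in t1.pairs) == sorted(
            (r, l) for r, l, _ in t2.pairs)


class TestAffinityModel:
    def test_zero_terms_returns_intercept(self):
        model = AffinityModel(contact_weights={k: 1.0 for k in "cc cp ca pp pa aa".split()},
                              nis_weights={}, intercept=-7.25)
        table = ContactTable(counts={}, pairs=[], threshold=5.5)
        assert binding_affinity(table, None, model) == pytest.approx(-7.25)

    def test_unit_weight_dot_product(self):
        model = AffinityModel(contact_weights={k: 1.0 for k in "cc cp ca pp pa aa".split()},
                              nis_weights={}, intercept=-1.0)
        table = ContactTable(counts={"pp": 2, "aa": 3}, pairs=[], threshold=5.5)
        assert binding_affinity(table, None, model) == pytest.approx(4.0)

    def test_random_weights_match_explicit_summation(self):
        rng = np.random.default_rng(8)
        keys = "cc cp ca pp pa aa".split()
        for _ in range(20):
            weights = {k: float(rng.normal()) for k in keys}
            counts = {k: int(rng.integers(0, 30)) for k in keys}
            nis = {"apolar": float(rng.uniform(0, 60)), "charged": float(rng.uniform(0, 40))}
            nis_w = {"apolar": float(rng.normal()), "charged": float(rng.normal())}
            intercept = float(rng.normal())
            model = AffinityModel(contact_weights=weights, nis_weights=nis_w,
                                  intercept=intercept)
            table = ContactTable(counts=dict(counts), pairs=[], threshold=5.5)
            expected = intercept + sum(weights[k] * counts[k] for k in keys) \
                + sum(nis_w[k] * nis[k] for k in nis)
            assert binding_affinity(table, nis, model) == pytest.approx(expected)

    def test_missing_weight_rejected(self):
        model = AffinityModel(contact_weights={"pp": 1.0}, nis_weights={}, intercept=0.0)
        table = ContactTable(counts={"aa": 1}, pairs=[], threshold=5.5)
        with pytest.raises(KeyError):
            binding_affinity(table, None, model)

    def test_default_scheme_covers_all_residues(self):
        scheme = ResidueClassScheme.default()
        assert {scheme.of(aa) for aa in "ACDEFGHIKLMNPQRSTVWY"} == \
            {"polar", "apolar", "charged"}
        assert class_pair_key("charged", "apolar") == class_pair_key("apolar", "charged")


class TestKdConversion:
    def test_zero_dg_gives_unit_kd(self):
        assert kd_from_dg(0.0) == pytest.approx(1.0)

    def test_round_trip_through_nanomolar(self):
        dg = GAS_CONSTANT * 298.15 * math.log(1e-9)
        assert kd_from_dg(dg) == pytest.approx(1e-9, rel=1e-12)
        assert dg_from_kd(1e-9) == pytest.approx(dg)

    def test_published_pair_consistent_within_rounding(self):
        # printed (-8.1 kcal/mol, 1.1e-6 M): ΔG is rounded to 0.1, so the
        # conversion must land within the +-0.05 kcal/mol rounding band
        kd = kd_from_dg(-8.1)
        assert kd == pytest.approx(1.16e-6, rel=0.01)
        assert abs(dg_from_kd(1.1e-6) - (-8.1)) <= 0.06

    def test_invalid_temperature_rejected(self):
        with pytest.raises(ValueError):
            kd_from_dg(-5.0, temperature=0.0)
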