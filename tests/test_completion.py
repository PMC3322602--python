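"""Energy typing, restraint enumeration, parameter lookup, perception."""

import itertools

import numpy as np
import pytest

from linksmith import completion, fixtures, idealizer
from linksmith.completion import (
    PdbAtom,
    assign_energy_types,
    complete_description,
    enumerate_angles,
    perceive_graph,
    read_pdb_atoms,
    targets_from_coordinates,
)
from linksmith.errors import CoordinateError
from linksmith.molgraph import AtomSpec, BondSpec, MonomerDescription


def brute_force_angle_count(desc):
    """Independent oracle: count bonded i-j-k paths by pair enumeration."""
    names = list(desc.atoms)
    bonded = {frozenset((b.atom1, b.atom2)) for b in desc.bonds}
    count = 0
    for i, j, k in itertools.permutations(names, 3):
        if i < k and frozenset((i, j)) in bonded and frozenset((j, k)) in bonded:
            count += 1
    return count


class TestEnergyTypes:
    def test_carbonyl_carbon_is_sp2(self, gly):
        typed = assign_energy_types(gly)
        assert typed.atoms["C"].energy_type.startswith("C2")
        assert typed.atoms["CA"].energy_type.startswith("C3")

    def test_aldimine_carbon_becomes_sp2(self, plp):
        # C4A carries the C4A=O4A double bond: sp2, non-ring
        typed = assign_energy_types(plp)
        assert typed.atoms["C4A"].energy_type == "C2h1"
        assert "r" in typed.atoms["C4"].energy_type

    def test_typing_is_deterministic(self, lys):
        t1 = assign_energy_types(lys)
        t2 = assign_energy_types(lys)
        assert {n: a.energy_type for n, a in t1.atoms.items()} == \
               {n: a.energy_type for n, a in t2.atoms.items()}

    def test_amide_nitrogen_typed_planar(self, table):
        desc = MonomerDescription(code="AMD")
        for name, el in [("C1", "C"), ("O1", "O"), ("N1", "N"),
                         ("C2", "C")]:
            desc.add_atom(AtomSpec(name, el, parent_ref=name))
        desc.add_bond(BondSpec("C1", "O1", "double"))
        desc.add_bond(BondSpec("C1", "N1"))
        desc.add_bond(BondSpec("N1", "C2"))
        typed = assign_energy_types(desc)
        assert typed.atoms["N1"].energy_type.startswith("N2")


class TestCompleteDescription:
    def test_linear_chain_single_angle(self, table):
        desc = MonomerDescription(code="CHN")
        for n, el in [("A", "C"), ("B", "C"), ("C", "C")]:
            desc.add_atom(AtomSpec(n, el, parent_ref=n))
        desc.add_bond(BondSpec("A", "B"))
        desc.add_bond(BondSpec("B", "C"))
        out = complete_description(desc, table)
        assert [(a.atom1, a.atom2, a.atom3) for a in out.angles] == \
            [("A", "B", "C")]
        assert out.level == "complete"

    @pytest.mark.parametrize("seed", range(20))
    def test_angle_count_matches_brute_force(self, seed, table):
        mon = fixtures.random_molecule(seed, 4 + seed % 9)
        out = complete_description(mon, table)
        assert len(out.angles) == brute_force_angle_count(out)
        # closed form: sum over atoms of deg*(deg-1)/2
        degs = [len(out.neighbours(n)) for n in out.atoms]
        assert len(out.angles) == sum(d * (d - 1) // 2 for d in degs)

    def test_gly_has_carboxylate_plane(self, gly):
        planes = [p for p in gly.planes if "C" in p.atoms]
        assert len(planes) == 1
        assert set(planes[0].atoms) >= {"C", "CA", "O", "OXT"}

    def test_every_bond_and_angle_has_target(self, library):
        for code, mon in library.monomers.items():
            for b in mon.bonds:
                assert b.target is not None and b.sigma > 0, (code, b)
            for a in mon.angles:
                assert a.target is not None and a.sigma > 0, (code, a)

    def test_restraints_independent_of_insertion_order(self, gly, table):
        shuffled = MonomerDescription(code="GLY", group="peptide")
        for name in reversed(list(gly.atoms)):
            a = gly.atoms[name]
            shuffled.add_atom(AtomSpec(a.name, a.element, parent_ref=a.name))
        for b in reversed(gly.bonds):
            shuffled.add_bond(BondSpec(b.atom1, b.atom2, b.order))
        out = complete_description(shuffled, table)
        assert {a.key: a.target for a in out.angles} == \
               {a.key: a.target for a in gly.angles}
        assert {t.key for t in out.torsions} == {t.key for t in gly.torsions}
        assert {frozenset(p.atoms) for p in out.planes} == \
               {frozenset(p.atoms) for p in gly.planes}

    def test_tetrahedral_phosphate_has_no_plane(self, plp):
        for plane in plp.planes:
            assert "P" not in plane.atoms


class TestParameterTable:
    def test_amide_bond_defined_with_sigma(self, table):
        target, sigma = table.bond("C2", "N2h1", "single")
        assert target == pytest.approx(1.329)
        assert sigma > 0

    def test_symmetric_under_reversal(self, table):
        assert table.bond("C2", "N2h1", "single") == \
               table.bond("N2h1", "C2", "single")
        assert table.angle("C3h1", "C2", "O2", 120.0) == \
               table.angle("O2", "C2", "C3h1", 120.0)

    def test_unknown_pair_falls_back_and_is_flagged(self, table):
        before = len(table.fallback_log)
        target, sigma = table.bond("Se3h1", "Se3h1", "single",
                                   elem1="SE", elem2="SE")
        assert target == pytest.approx(2 * table.radius("SE"))
        assert len(table.fallback_log) == before + 1


class TestPerception:
    def test_two_carbons_at_bonding_distance(self, table):
        atoms = [PdbAtom("C1", "C", (0, 0, 0)), PdbAtom("C2", "C", (1.53, 0, 0))]
        desc = perceive_graph(atoms, table)
        assert len(desc.bonds) == 1

    def test_two_carbons_too_far(self, table):
        atoms = [PdbAtom("C1", "C", (0, 0, 0)), PdbAtom("C2", "C", (3.0, 0, 0))]
        desc = perceive_graph(atoms, table)
        assert desc.bonds == []

    def test_overlapping_atoms_rejected(self, table):
        atoms = [PdbAtom("C1", "C", (0, 0, 0)), PdbAtom("C2", "C", (0.2, 0, 0))]
        with pytest.raises(CoordinateError, match="overlap"):
            perceive_graph(atoms, table)

    @pytest.mark.parametrize("code", ["GLY", "ALA", "CYS", "LYS", "PLP", "GLC"])
    def test_idealized_fixture_recovers_heavy_graph(self, code, library, table):
        mon = library.monomers[code]
        coords = idealizer.embed(mon, seed=11)
        coords, report = idealizer.regularize(mon, coords)
        atoms = [PdbAtom(n, mon.atoms[n].element, tuple(coords[n]))
                 for n in mon.atoms]
        desc = perceive_graph(atoms, table, code=code)

        def heavy_bonds(d):
            return {frozenset((b.atom1, b.atom2)) for b in d.bonds
                    if not d.atoms[b.atom1].is_hydrogen
                    and not d.atoms[b.atom2].is_hydrogen}

        assert heavy_bonds(desc) == heavy_bonds(mon)

    def test_pdb_atom_parsing_with_element_fallback(self):
        text = ("HETATM    1  C4A PLP A   1       1.000   2.000   3.000"
                "  1.00 20.00           C\n"
                "HETATM    2  O4A PLP A   1       2.300   2.000   3.000"
                "  1.00 20.00\n")
        atoms = read_pdb_atoms(text)
        assert [a.name for a in atoms] == ["C4A", "O4A"]
        assert atoms[0].element == "C"
        assert atoms[1].element == "O"  # derived from the name
        assert atoms[0].xyz == (1.0, 2.0, 3.0)


class TestTargetsFromCoordinates:
    def test_observed_bond_becomes_target(self, table):
        desc = MonomerDescription(code="TWO")
        desc.add_atom(AtomSpec("C1", "C", parent_ref="C1"))
        desc.add_atom(AtomSpec("C2", "C", parent_ref="C2"))
        desc.add_bond(BondSpec("C1", "C2"))
        out = targets_from_coordinates(
            desc, {"C1": (0, 0, 0), "C2": (1.48, 0, 0)}, table)
        assert out.bonds[0].target == pytest.approx(1.48)
        assert out.level == "complete"

    def test_collinear_atoms_give_180(self, table):
        desc = MonomerDescription(code="LIN")
        for i, n in enumerate(["A", "B", "C"]):
            desc.add_atom(AtomSpec(n, "C", parent_ref=n))
        desc.add_bond(BondSpec("A", "B"))
        desc.add_bond(BondSpec("B", "C"))
        out = targets_from_coordinates(
            desc, {"A": (0, 0, 0), "B": (1.5, 0, 0), "C": (3.0, 0, 0)}, table)
        assert out.angles[0].target == pytest.approx(180.0)

    def test_idealized_coordinates_reproduce_dictionary(self, gly, table):
        coords = idealizer.embed(gly, seed=23)
        coords, _ = idealizer.regularize(gly, coords)
        out = targets_from_coordinates(gly, coords, table)
        for bond in out.bonds:
            ref = gly.bond_between(bond.atom1, bond.atom2)
            assert bond.target == pytest.approx(ref.target, abs=1e-3)

    def test_missing_coordinate_is_named(self, gly, table):
        with pytest.raises(CoordinateError, match="N"):
            targets_from_coordinates(gly, {}, table)
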