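"""Graph model: editing, journal replay, hydrogens, chirality, validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linksmith import fixtures
from linksmith.errors import EditError, ValenceError
from linksmith.molgraph import (
    AtomSpec,
    BondSpec,
    GraphEdit,
    MonomerDescription,
    adjust_hydrogens,
    apply_edit,
    chiral_volume,
    chirality_sign,
    effective_valence,
    replay_journal,
    validate,
)


def simple_chain(*elements):
    desc = MonomerDescription(code="TST")
    prev = None
    for i, el in enumerate(elements):
        name = f"{el}{i + 1}"
        desc.add_atom(AtomSpec(name, el, parent_ref=name))
        if prev is not None:
            desc.add_bond(BondSpec(prev, name))
        prev = name
    return desc


class TestApplyEdit:
    def test_delete_atom_removes_bonds_and_restraints(self, plp):
        out = apply_edit(plp, GraphEdit("delete_atom", {"name": "O4A"}))
        assert "O4A" not in out.atoms
        assert len(out.atoms) == len(plp.atoms) - 1
        for bond in out.bonds:
            assert "O4A" not in (bond.atom1, bond.atom2)
        for ang in out.angles:
            assert "O4A" not in (ang.atom1, ang.atom2, ang.atom3)
        for plane in out.planes:
            assert "O4A" not in plane.atoms
        assert out.journal[-1].kind == "delete_atom"

    def test_delete_oxt_matches_carboxyl_pattern(self, gly):
        out = apply_edit(gly, GraphEdit("delete_atom", {"name": "OXT"}))
        assert out.journal[-1] == GraphEdit("delete_atom", {"name": "OXT"})
        assert "OXT" not in out.atoms

    def test_add_then_delete_is_identity(self, gly):
        added = apply_edit(gly, GraphEdit(
            "add_atom", {"atom": AtomSpec("XX", "C")}))
        assert added.atoms["XX"].parent_ref is None
        back = apply_edit(added, GraphEdit("delete_atom", {"name": "XX"}))
        assert list(back.atoms) == list(gly.atoms)
        assert [b.key for b in back.bonds] == [b.key for b in gly.bonds]

    @pytest.mark.parametrize("edit,err", [
        (GraphEdit("delete_atom", {"name": "NOPE"}), "NOPE"),
        (GraphEdit("add_atom", {"atom": AtomSpec("CA", "C")}), "CA"),
        (GraphEdit("add_bond", {"atom1": "CA", "atom2": "CA"}), "CA"),
    ])
    def test_bad_edits_name_the_offender(self, gly, edit, err):
        with pytest.raises(EditError, match=err):
            apply_edit(gly, edit)

    def test_journal_replay_reproduces_edits(self, lys):
        edits = [
            GraphEdit("delete_atom", {"name": "HZ3"}),
            GraphEdit("add_atom", {"atom": AtomSpec("CX", "C")}),
            GraphEdit("add_bond", {"atom1": "NZ", "atom2": "CX"}),
            GraphEdit("change_bond", {"atom1": "NZ", "atom2": "CX",
                                      "order": "double"}),
        ]
        edited = lys
        for e in edits:
            edited = apply_edit(edited, e)
        replayed = replay_journal(lys, edited.journal)
        assert list(replayed.atoms) == list(edited.atoms)
        assert [(b.atom1, b.atom2, b.order) for b in replayed.bonds] == \
               [(b.atom1, b.atom2, b.order) for b in edited.bonds]


class TestHydrogens:
    def test_sp3_carbon_gains_named_hydrogen(self):
        desc = simple_chain("C", "C", "C")
        desc.add_atom(AtomSpec("C4", "C", parent_ref="C4"))
        desc.add_bond(BondSpec("C2", "C4"))
        out, edits = adjust_hydrogens(desc)
        # central carbon C2 has 3 heavy bonds -> exactly one H named from it
        assert out.hydrogens_on("C2") == ["H21"]
        assert any(e.kind == "add_atom" for e in edits)

    def test_amide_nitrogen_keeps_single_hydrogen(self):
        # N bonded to two heavy atoms (amide-like after linking)
        desc = simple_chain("C", "N", "C")
        for h in ("HN1", "HN2", "HN3"):
            desc.add_atom(AtomSpec(h, "H"))
            desc.add_bond(BondSpec("N2", h))
        out, edits = adjust_hydrogens(desc)
        assert len(out.hydrogens_on("N2")) == 1
        deleted = [e for e in edits if e.kind == "delete_atom"]
        assert len(deleted) == 2

    def test_saturated_ether_oxygen_unchanged(self):
        desc = simple_chain("C", "O", "C")
        for carbon in ("C1", "C3"):
            for i in range(1, 4):
                h = f"H{carbon[1]}{i}"
                desc.add_atom(AtomSpec(h, "H"))
                desc.add_bond(BondSpec(carbon, h))
        out, edits = adjust_hydrogens(desc)
        assert edits == []
        assert list(out.atoms) == list(desc.atoms)
        assert out.hydrogens_on("O2") == []

    def test_idempotent(self, library):
        for code, mon in library.monomers.items():
            once, edits1 = adjust_hydrogens(mon)
            twice, edits2 = adjust_hydrogens(once)
            assert edits2 == [], code
            assert list(twice.atoms) == list(once.atoms)

    def test_overvalent_atom_is_reported(self):
        desc = simple_chain("C", "C")
        for i in range(4):
            desc.add_atom(AtomSpec(f"X{i}", "O"))
            desc.add_bond(BondSpec("C1", f"X{i}"))
        with pytest.raises(ValenceError, match="C1"):
            adjust_hydrogens(desc)

    def test_charge_shifts_valence(self):
        assert effective_valence("N", +1) == 4
        assert effective_valence("O", -1) == 1
        assert effective_valence("C") == 4


class TestChiralVolume:
    def test_unit_axes_give_plus_one(self):
        c = (0.0, 0.0, 0.0)
        v = chiral_volume(c, (1, 0, 0), (0, 1, 0), (0, 0, 1))
        assert v == pytest.approx(1.0)

    def test_swap_flips_sign(self):
        c = (0.0, 0.0, 0.0)
        v = chiral_volume(c, (0, 1, 0), (1, 0, 0), (0, 0, 1))
        assert v == pytest.approx(-1.0)

    def test_coplanar_is_degenerate(self):
        c = (0.0, 0.0, 0.0)
        v = chiral_volume(c, (1, 0, 0), (0, 1, 0), (1, 1, 0))
        assert v == pytest.approx(0.0)
        assert chirality_sign(v) == "degenerate"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_permutation_parity(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3))
        v = chiral_volume(*pts)
        # even permutation of the three neighbours preserves the volume
        assert chiral_volume(pts[0], pts[2], pts[3], pts[1]) == pytest.approx(v)
        # odd permutation flips it
        assert chiral_volume(pts[0], pts[2], pts[1], pts[3]) == pytest.approx(-v)


class TestValidate:
    def test_fixture_monomers_are_clean(self, library):
        for code, mon in library.monomers.items():
            assert validate(mon) == [], code

    def test_dangling_bond_reference(self, gly):
        gly.bonds.append(BondSpec("CA", "XX"))
        findings = [f for f in validate(gly) if f.kind == "dangling-reference"]
        assert len(findings) == 1
        assert "XX" in findings[0].message

    def test_duplicate_atom_name(self, gly):
        gly.atoms["CA_2"] = AtomSpec("CA", "C")
        findings = [f for f in validate(gly) if f.kind == "duplicate-name"]
        assert len(findings) == 1

    def test_disconnected_fragment(self):
        desc = simple_chain("C", "C")
        desc.add_atom(AtomSpec("O9", "O"))
        findings = [f for f in validate(desc) if f.kind == "disconnected"]
        assert len(findings) == 1
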