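"""Composite sessions: compose, regularize, split, apply, save."""

import numpy as np
import pytest

from linksmith import cif_io, fixtures, linkgen
from linksmith.entries import ModAngleEdit, ModAtomEdit
from linksmith.errors import (
    EditError,
    GroupMismatchError,
    SerializationError,
    SessionError,
    ValenceError,
)
from linksmith.linkgen import (
    _diff_monomer,
    apply_link,
    apply_modification,
    compose,
    composite_signature,
    make_unique_names,
    regularize_session,
    save_additional_library,
    side_naming,
    split,
)
from linksmith.molgraph import GraphEdit, apply_edit, validate


@pytest.fixture(scope="module")
def lysplp_session(library):
    lys = library.monomers["LYS"]
    plp = library.monomers["PLP"]
    edited = apply_edit(plp, GraphEdit("delete_atom", {"name": "O4A"}))
    session = compose(lys, edited, ("NZ", "C4A", "double"),
                      original_a=lys, original_b=plp)
    return regularize_session(session, seed=1)


class TestCompose:
    def test_unknown_endpoint_is_rejected(self, lys, plp):
        with pytest.raises(EditError, match="QQ"):
            compose(lys, plp, ("NZ", "QQ", "single"))

    def test_two_copies_of_one_compound(self, library):
        cys = library.monomers["CYS"]
        session = compose(cys, cys, ("SG", "SG", "single"))
        make_unique_names(session)
        assert session.unique_names[(1, "SG")] != session.unique_names[(2, "SG")]

    def test_split_requires_regularization(self, lys, plp):
        session = compose(lys, plp, ("NZ", "C4A", "single"))
        with pytest.raises(SessionError):
            split(session)

    def test_link_bond_order_stays_editable(self, lys, plp):
        session = compose(lys, plp, ("NZ", "C4A", "single"))
        session.set_link_bond_order(0, "double")
        assert session.link_bonds[0][2] == "double"


class TestUniqueNames:
    @pytest.mark.parametrize("pair", [("CYS", "CYS"), ("GLY", "ALA"),
                                      ("LYS", "PLP"), ("GLC", "GLC")])
    def test_renaming_is_bijective_and_restorable(self, library, pair):
        a = library.monomers[pair[0]]
        b = library.monomers[pair[1]]
        unique, restore = side_naming(a, b)
        assert len(unique) == len(a.atoms) + len(b.atoms)
        assert len(set(unique.values())) == len(unique)
        for key, uname in unique.items():
            assert restore[uname] == key
            assert len(uname) <= 4


class TestRegularizeSession:
    def test_lys_plp_composite_converges(self, lysplp_session):
        report = lysplp_session.report
        assert report.converged
        assert report.max_deviation("bond") <= 0.01
        assert report.max_deviation("angle") <= 1.0

    def test_surplus_amine_hydrogens_removed_automatically(self, lysplp_session):
        deletions = [e.payload["name"] for e in lysplp_session.auto_edits[1]
                     if e.kind == "delete_atom"]
        assert len(deletions) == 2
        assert all(d.startswith("HZ") for d in deletions)

    def test_unremoved_aldehyde_oxygen_is_a_valence_error(self, lys, plp):
        session = compose(lys, plp, ("NZ", "C4A", "double"))
        with pytest.raises(ValenceError, match="C4A"):
            regularize_session(session, seed=1)

    def test_gly_gly_dipeptide_with_pre_deleted_carboxyl(self, library):
        gly = library.monomers["GLY"]
        edited = gly
        for name in ("OXT", "HXT"):
            edited = apply_edit(edited, GraphEdit("delete_atom", {"name": name}))
        session = compose(edited, gly, ("C", "N", "single"), original_a=gly,
                          original_b=gly)
        regularize_session(session, seed=3)
        assert session.report.converged
        mod_a, mod_b, link = split(session)
        assert mod_a.id == "GLYmod1" and mod_b.id == "GLYmod2"
        assert link.id == "GLY-GLY"


class TestSplit:
    def test_lys_plp_entry_structure(self, lysplp_session):
        mod_a, mod_b, link = split(lysplp_session)
        # the link holds the new covalent bond with both side labels
        bonds = [(b.side1, b.atom1, b.side2, b.atom2, b.order)
                 for b in link.bonds]
        assert bonds == [(1, "NZ", 2, "C4A", "double")]
        # every link angle spans the bond
        for ang in link.angles:
            assert len(set(ang.sides)) == 2
        # the aldehyde-oxygen deletion lives in the PLP modification
        plp_deletes = [e.atom_id for e in mod_b.atom_edits
                       if e.function == "delete"]
        assert "O4A" in plp_deletes
        # the amine deprotonation lives in the LYS modification
        lys_deletes = [e.atom_id for e in mod_a.atom_edits
                       if e.function == "delete"]
        assert sorted(lys_deletes) == ["HZ2", "HZ3"]

    def test_link_restraints_touch_both_sides(self, lysplp_session):
        _, _, link = split(lysplp_session)
        assert link.crosses_sides()
        for tor in link.torsions:
            assert len(set(tor.sides)) == 2
        plane_sides = {}
        for row in link.planes:
            plane_sides.setdefault(row.plane_id, set()).add(row.side)
        for sides in plane_sides.values():
            assert sides == {1, 2}

    def test_split_is_deterministic(self, library):
        def build():
            lys = library.monomers["LYS"]
            plp = apply_edit(library.monomers["PLP"],
                             GraphEdit("delete_atom", {"name": "O4A"}))
            s = compose(lys, plp, ("NZ", "C4A", "double"),
                        original_a=library.monomers["LYS"],
                        original_b=library.monomers["PLP"])
            regularize_session(s, seed=5)
            _, text = save_additional_library(s, base_library=library)
            return text

        assert build() == build()


class TestChangeDetection:
    def _angle_shift(self, gly, factor):
        edited = gly.copy()
        target = edited.angles[0]
        target.target = round(target.target + factor * target.sigma, 2)
        return _diff_monomer("GLYmod1", gly, edited)

    def test_sub_sigma_shift_is_not_recorded(self, gly):
        mod = self._angle_shift(gly, 0.5)
        assert mod.angle_edits == []

    def test_super_sigma_shift_becomes_change_record(self, gly):
        mod = self._angle_shift(gly, 2.0)
        changes = [e for e in mod.angle_edits if e.function == "change"]
        assert len(changes) == 1

    def test_retyped_atom_forces_bond_change_record(self, gly):
        edited = gly.copy()
        edited.atoms["N"].energy_type = "Nxx"
        mod = _diff_monomer("GLYmod1", gly, edited)
        changed_bonds = {frozenset((e.atom1, e.atom2))
                         for e in mod.bond_edits if e.function == "change"}
        assert frozenset(("N", "CA")) in changed_bonds


class TestApplyModification:
    def test_del_oxt_on_ala_updates_plane(self, library, ala):
        out = apply_modification(ala, library.modifications["DEL-OXT"])
        assert "OXT" not in out.atoms and "HXT" not in out.atoms
        assert validate(out) == []
        carboxyl = [p for p in out.planes if "C" in p.atoms]
        assert carboxyl and "OXT" not in carboxyl[0].atoms

    def test_empty_modification_is_identity(self, gly):
        from linksmith.entries import ModificationEntry
        out = apply_modification(gly, ModificationEntry(id="NOP"))
        assert out.atoms == gly.atoms and out.bonds == gly.bonds

    def test_delete_of_absent_atom_is_mismatch(self, gly):
        from linksmith.entries import ModificationEntry
        mod = ModificationEntry(id="BAD", atom_edits=[
            ModAtomEdit("delete", atom_id="SG")])
        with pytest.raises(EditError, match="SG"):
            apply_modification(gly, mod)

    def test_diff_of_applied_modification_reproduces_it(self, library, ala):
        mod = library.modifications["DEL-OXT"]
        out = apply_modification(ala, mod)
        rediff = _diff_monomer("X", ala, out)
        assert sorted(e.atom_id for e in rediff.atom_edits
                      if e.function == "delete") == ["HXT", "OXT"]
        assert not [e for e in rediff.atom_edits if e.function == "add"]


class TestApplyLink:
    def test_trans_link_builds_dipeptide(self, library, gly):
        dipep = apply_link(gly, gly, library.modifications["DEL-OXT"],
                           library.modifications["NH1"],
                           library.links["TRANS"])
        amide = dipep.bond_between("C1", "N2")
        assert amide is not None and amide.target == pytest.approx(1.329)
        assert validate(dipep) == []

    def test_group_constraint_is_enforced(self, library, glc, gly):
        with pytest.raises(GroupMismatchError):
            apply_link(glc, gly, library.modifications["DEL-O1"],
                       library.modifications["NH1"], library.links["TRANS"])

    def test_pyranose_link_rejects_peptide_side(self, library, glc, gly):
        # 1-4 glycosidic link is generic for pyranoses only
        with pytest.raises(GroupMismatchError):
            apply_link(glc, gly, library.modifications["DEL-O1"],
                       library.modifications["DEL-HO4"],
                       library.links["ALPHA1-4"])


class TestRoundTrip:
    def check(self, library, code_a, code_b, atom_a, atom_b, seed):
        mon_a = library.monomers[code_a]
        mon_b = library.monomers[code_b]
        session = compose(mon_a, mon_b, (atom_a, atom_b, "single"))
        regularize_session(session, seed=seed)
        mod_a, mod_b, link = split(session)
        applied = apply_link(mon_a, mon_b, mod_a, mod_b, link)
        a2 = apply_modification(mon_a, mod_a)
        b2 = apply_modification(mon_b, mod_b)
        _, restore = side_naming(a2, b2)
        assert composite_signature(applied, restore) == \
            composite_signature(session.composite, session.restore_names)

    @pytest.mark.parametrize("code_a,code_b,atom_a,atom_b", [
        ("GLY", "ALA", "CA", "CB"),
        ("CYS", "CYS", "SG", "SG"),
        ("LYS", "GLC", "NZ", "C6"),
    ])
    def test_apply_of_split_reproduces_composite(self, library, code_a,
                                                 code_b, atom_a, atom_b):
        self.check(library, code_a, code_b, atom_a, atom_b, seed=17)


class TestSaveAdditionalLibrary:
    def test_five_blocks_when_both_monomers_resolvable(self, lysplp_session,
                                                       library):
        _, text = save_additional_library(lysplp_session,
                                          base_library=library)
        blocks = [l for l in text.splitlines() if l.startswith("data_")]
        assert blocks == ["data_mod_list", "data_link_list",
                          "data_mod_LYSmod1", "data_mod_PLPmod1",
                          "data_link_LYS-PLP"]

    def test_six_blocks_when_one_monomer_is_new(self, lysplp_session,
                                                library):
        base = cif_io.RestraintLibrary()
        base.monomers["LYS"] = library.monomers["LYS"]
        _, text = save_additional_library(lysplp_session, base_library=base)
        blocks = [l for l in text.splitlines() if l.startswith("data_")]
        assert len(blocks) == 6 and "data_comp_PLP" in blocks

    def test_append_gives_precedence_and_warns(self, lysplp_session, library,
                                               tmp_path):
        path = tmp_path / "add.cif"
        save_additional_library(lysplp_session, path=path,
                                base_library=library)
        lib2, _ = save_additional_library(lysplp_session, path=path,
                                          mode="append",
                                          base_library=library)
        assert any("shadow" in w for w in lib2.warnings)
        assert lib2.provenance[("link", "LYS-PLP")] == "additional"

    def test_new_mode_refuses_existing_ids(self, lysplp_session, library,
                                           tmp_path):
        path = tmp_path / "add.cif"
        save_additional_library(lysplp_session, path=path,
                                base_library=library)
        with pytest.raises(SerializationError):
            save_additional_library(lysplp_session, path=path, mode="new",
                                    base_library=library)

    def test_saved_library_reloads_and_reapplies(self, lysplp_session,
                                                 library, tmp_path):
        _, text = save_additional_library(lysplp_session,
                                          base_library=library)
        loaded = cif_io.read_library(text)
        dimer = apply_link(library.monomers["LYS"], library.monomers["PLP"],
                           loaded.modifications["LYSmod1"],
                           loaded.modifications["PLPmod1"],
                           loaded.links["LYS-PLP"])
        assert validate(dimer) == []
        # the Schiff-base bond came back through the CIF layer
        u, _ = side_naming(
            apply_modification(library.monomers["LYS"],
                               loaded.modifications["LYSmod1"]),
            apply_modification(library.monomers["PLP"],
                               loaded.modifications["PLPmod1"]))
        bond = dimer.bond_between(u[(1, "NZ")], u[(2, "C4A")])
        assert bond is not None and bond.order == "double"
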