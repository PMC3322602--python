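"""Dictionary CIF dialect: parsing, serialization, round trips, precedence."""

import pytest

from linksmith import cif_io, fixtures
from linksmith.errors import ConsistencyError, LibraryParseError, SerializationError
from linksmith.molgraph import AtomSpec, BondSpec, MonomerDescription

MINIMAL_DOC = """\
data_comp_list
loop_
_chem_comp.id
_chem_comp.three_letter_code
_chem_comp.name
_chem_comp.group
_chem_comp.number_atoms_all
_chem_comp.number_atoms_nh
_chem_comp.desc_level
XYZ XYZ 'test compound' non-polymer 2 2 M

data_comp_XYZ
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.type_energy
_chem_comp_atom.partial_charge
XYZ C1 C . 0
XYZ O1 O . 0
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.type
_chem_comp_bond.value_dist
_chem_comp_bond.value_dist_esd
XYZ C1 O1 double . .
"""


class TestRead:
    def test_minimal_monomer_block(self):
        lib = cif_io.read_library(MINIMAL_DOC)
        assert list(lib.monomers) == ["XYZ"]
        assert not lib.modifications and not lib.links
        mon = lib.monomers["XYZ"]
        assert mon.level == "minimal"
        assert len(mon.atoms) == 2 and len(mon.bonds) == 1
        assert mon.bonds[0].order == "double"
        assert mon.bonds[0].target is None

    def test_malformed_document_raises_parse_error(self):
        with pytest.raises(LibraryParseError):
            cif_io.read_library("data_comp_X\nloop_\n_chem_comp_atom.atom_id "
                                "value-outside-loop\n_tag\n")

    def test_list_without_entry_block_is_inconsistent(self):
        doc = MINIMAL_DOC.replace("data_comp_XYZ", "data_comp_ZZZ") \
                         .replace("XYZ C1", "ZZZ C1").replace("XYZ O1", "ZZZ O1") \
                         .replace("XYZ C1 O1", "ZZZ C1 O1")
        with pytest.raises(ConsistencyError, match="XYZ"):
            cif_io.read_library(doc)

    def test_missing_esd_gets_documented_default(self):
        doc = MINIMAL_DOC.replace("XYZ C1 O1 double . .",
                                  "XYZ C1 O1 double 1.230 .")
        lib = cif_io.read_library(doc)
        assert lib.monomers["XYZ"].bonds[0].sigma == cif_io.DEFAULT_BOND_SIGMA

    def test_unknown_categories_survive_round_trip(self):
        doc = MINIMAL_DOC + (
            "loop_\n_chem_comp_tree.comp_id\n_chem_comp_tree.atom_id\n"
            "XYZ C1\nXYZ O1\n")
        lib = cif_io.read_library(doc)
        text = cif_io.write_library(lib)
        assert "_chem_comp_tree.atom_id" in text
        assert cif_io.write_library(cif_io.read_library(text)) == text


class TestWrite:
    def test_empty_library_round_trips_to_empty(self):
        text = cif_io.write_library(cif_io.RestraintLibrary())
        lib = cif_io.read_library(text)
        assert not lib.monomers and not lib.modifications and not lib.links

    def test_refuses_dangling_reference(self):
        mon = MonomerDescription(code="BAD")
        mon.add_atom(AtomSpec("C1", "C"))
        mon.bonds.append(BondSpec("C1", "QQ"))
        lib = cif_io.RestraintLibrary(monomers={"BAD": mon})
        with pytest.raises(SerializationError, match="BAD"):
            cif_io.write_library(lib)

    def test_quoting_of_awkward_values(self):
        mon = MonomerDescription(code="AWK", name="5'-phosphate thing")
        mon.add_atom(AtomSpec("C1", "C"))
        text = cif_io.write_library(
            cif_io.RestraintLibrary(monomers={"AWK": mon}))
        lib = cif_io.read_library(text)
        assert lib.monomers["AWK"].name == "5'-phosphate thing"


class TestRoundTrip:
    def test_semantic_identity_on_fixture_library(self, library):
        text = cif_io.write_library(library)
        back = cif_io.read_library(text)
        assert back.monomers == library.monomers
        assert back.modifications == library.modifications
        assert back.links == library.links

    def test_double_write_is_byte_identical(self, library):
        first = cif_io.write_library(library)
        second = cif_io.write_library(cif_io.read_library(first))
        assert first == second

    def test_random_monomer_round_trip(self, table):
        from linksmith.completion import complete_description
        lib = cif_io.RestraintLibrary()
        for seed in range(50):
            mon = fixtures.random_molecule(seed, 3 + seed % 9)
            mon.code = f"R{seed:02d}"
            lib.monomers[mon.code] = complete_description(mon, table)
        first = cif_io.write_library(lib)
        second = cif_io.write_library(cif_io.read_library(first))
        assert first == second


class TestPrecedence:
    def test_additional_entry_shadows_standard(self, library):
        extra = cif_io.RestraintLibrary()
        mine = MonomerDescription(code="GLY", name="my glycine")
        mine.add_atom(AtomSpec("C1", "C"))
        extra.monomers["GLY"] = mine
        merged = cif_io.merge_libraries(library, extra)
        assert merged.monomers["GLY"].name == "my glycine"
        assert merged.provenance[("comp", "GLY")] == "additional"
        assert any("shadow" in w for w in merged.warnings)
        # non-colliding entries fall through from the standard side
        assert "PLP" in merged.monomers
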