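"""Built-in fragment library and generators for tests and examples.

The fragment set is hand-encoded from standard small-molecule chemistry:
glycine, alanine, cysteine, lysine (protonated side-chain amine),
pyridoxal-5'-phosphate (PLP, with its aldehyde oxygen O4A) and an
alpha-D-glucopyranose, together with the generic modifications and links
that the peptide, disulfide and glycosidic linkage machinery needs
(carboxyl-terminus deletion, amino-group deprotonation, anomeric and
hydroxyl deletions, amide/disulfide/1-4 glycosidic links).

Chirality signs are geometric (signed volume of the ordered
centre-to-neighbour vectors) and were fixed from reference 3D structures
of the L-amino acids and alpha-D-glucose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cif_io import RestraintLibrary
from .completion import ParameterTable, complete_description, load_parameter_table
from .entries import (
    LinkAngle,
    LinkBond,
    LinkChiral,
    LinkEntry,
    LinkPlaneAtom,
    LinkTorsion,
    ModAtomEdit,
    ModificationEntry,
)
from .errors import LinksmithError
from .molgraph import (
    AtomSpec,
    BondSpec,
    ChiralCenter,
    MonomerDescription,
    adjust_hydrogens,
    effective_valence,
)

__all__ = [
    "DesignScheme",
    "builtin_fragments",
    "builtin_parameter_table",
    "builtin_amino_codes",
    "random_molecule",
    "count_design_entries",
]


# ---------------------------------------------------------------------------
# monomer builders


def _mol(code, name, group, atoms, bonds, chirals=()):
    desc = MonomerDescription(code=code, name=name, group=group,
                              level="minimal")
    for spec in atoms:
        aname, element = spec[0], spec[1]
        charge = spec[2] if len(spec) > 2 else 0
        desc.add_atom(AtomSpec(aname, element, charge=charge,
                               parent_ref=aname))
    for b in bonds:
        a1, a2 = b[0], b[1]
        order = b[2] if len(b) > 2 else "single"
        desc.add_bond(BondSpec(a1, a2, order))
    for i, (centre, n1, n2, n3, sign) in enumerate(chirals):
        desc.chirals.append(ChiralCenter(
            id=f"chir-{i + 1}", centre=centre, atom1=n1, atom2=n2, atom3=n3,
            sign=sign))
    return desc


def _backbone(extra_atoms, extra_bonds, n_ha):
    """Free amino acid: H2N-CA(-HA..)-COOH."""
    atoms = [("N", "N"), ("H", "H"), ("H2", "H"), ("CA", "C")]
    atoms += [(f"HA{i}" if n_ha > 1 else "HA", "H") for i in range(1, n_ha + 1)]
    atoms += [("C", "C"), ("O", "O"), ("OXT", "O"), ("HXT", "H")]
    bonds = [("N", "H"), ("N", "H2"), ("N", "CA")]
    bonds += [("CA", f"HA{i}" if n_ha > 1 else "HA") for i in range(1, n_ha + 1)]
    bonds += [("CA", "C"), ("C", "O", "double"), ("C", "OXT"),
              ("OXT", "HXT")]
    return atoms + extra_atoms, bonds + extra_bonds


def _gly():
    atoms, bonds = _backbone([], [], n_ha=2)
    return _mol("GLY", "glycine", "peptide", atoms, bonds)


#: L-amino-acid CA handedness: signed volume of (N, CB, C) is negative
_L_ALPHA = ("CA", "N", "CB", "C", "negative")


def _ala():
    atoms, bonds = _backbone(
        [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("HB3", "H")],
        [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3")], n_ha=1)
    return _mol("ALA", "alanine", "peptide", atoms, bonds, [_L_ALPHA])


def _cys():
    atoms, bonds = _backbone(
        [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("SG", "S"), ("HG", "H")],
        [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "SG"),
         ("SG", "HG")], n_ha=1)
    return _mol("CYS", "cysteine", "peptide", atoms, bonds, [_L_ALPHA])


def _lys():
    side = [("CB", "C"), ("HB1", "H"), ("HB2", "H"),
            ("CG", "C"), ("HG1", "H"), ("HG2", "H"),
            ("CD", "C"), ("HD1", "H"), ("HD2", "H"),
            ("CE", "C"), ("HE1", "H"), ("HE2", "H"),
            ("NZ", "N", 1), ("HZ1", "H"), ("HZ2", "H"), ("HZ3", "H")]
    side_bonds = [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"),
                  ("CB", "CG"), ("CG", "HG1"), ("CG", "HG2"),
                  ("CG", "CD"), ("CD", "HD1"), ("CD", "HD2"),
                  ("CD", "CE"), ("CE", "HE1"), ("CE", "HE2"),
                  ("CE", "NZ"), ("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")]
    atoms, bonds = _backbone(side, side_bonds, n_ha=1)
    return _mol("LYS", "lysine", "peptide", atoms, bonds, [_L_ALPHA])


def _plp():
    atoms = [("N1", "N"), ("C2", "C"), ("C2A", "C"),
             ("H2A1", "H"), ("H2A2", "H"), ("H2A3", "H"),
             ("C3", "C"), ("O3", "O"), ("HO3", "H"),
             ("C4", "C"), ("C4A", "C"), ("H4A", "H"), ("O4A", "O"),
             ("C5", "C"), ("C5A", "C"), ("H5A1", "H"), ("H5A2", "H"),
             ("C6", "C"), ("H6", "H"),
             ("O4P", "O"), ("P", "P"), ("O1P", "O"),
             ("O2P", "O"), ("HOP2", "H"), ("O3P", "O"), ("HOP3", "H")]
    ring = [("N1", "C2", "aromatic"), ("C2", "C3", "aromatic"),
            ("C3", "C4", "aromatic"), ("C4", "C5", "aromatic"),
            ("C5", "C6", "aromatic"), ("C6", "N1", "aromatic")]
    bonds = ring + [
        ("C2", "C2A"), ("C2A", "H2A1"), ("C2A", "H2A2"), ("C2A", "H2A3"),
        ("C3", "O3"), ("O3", "HO3"),
        ("C4", "C4A"), ("C4A", "H4A"), ("C4A", "O4A", "double"),
        ("C5", "C5A"), ("C5A", "H5A1"), ("C5A", "H5A2"),
        ("C6", "H6"),
        ("C5A", "O4P"), ("O4P", "P"), ("P", "O1P", "double"),
        ("P", "O2P"), ("O2P", "HOP2"), ("P", "O3P"), ("O3P", "HOP3")]
    return _mol("PLP", "pyridoxal-5'-phosphate", "non-polymer", atoms, bonds)


def _glc():
    atoms = [("C1", "C"), ("H1", "H"), ("O1", "O"), ("HO1", "H"),
             ("C2", "C"), ("H2", "H"), ("O2", "O"), ("HO2", "H"),
             ("C3", "C"), ("H3", "H"), ("O3", "O"), ("HO3", "H"),
             ("C4", "C"), ("H4", "H"), ("O4", "O"), ("HO4", "H"),
             ("C5", "C"), ("H5", "H"),
             ("C6", "C"), ("H61", "H"), ("H62", "H"),
             ("O6", "O"), ("HO6", "H"), ("O5", "O")]
    bonds = [("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"),
             ("C5", "O5"), ("O5", "C1"),
             ("C1", "H1"), ("C1", "O1"), ("O1", "HO1"),
             ("C2", "H2"), ("C2", "O2"), ("O2", "HO2"),
             ("C3", "H3"), ("C3", "O3"), ("O3", "HO3"),
             ("C4", "H4"), ("C4", "O4"), ("O4", "HO4"),
             ("C5", "H5"), ("C5", "C6"),
             ("C6", "H61"), ("C6", "H62"), ("C6", "O6"), ("O6", "HO6")]
    # signed volumes measured on an alpha-D-glucopyranose reference model
    chirals = [("C1", "O1", "O5", "C2", "negative"),
               ("C2", "O2", "C1", "C3", "negative"),
               ("C3", "O3", "C2", "C4", "positive"),
               ("C4", "O4", "C3", "C5", "negative"),
               ("C5", "O5", "C4", "C6", "negative")]
    return _mol("GLC", "alpha-D-glucopyranose", "pyranose", atoms, bonds,
                chirals)


# ---------------------------------------------------------------------------
# generic modifications and links


def _mods():
    del_oxt = ModificationEntry(
        id="DEL-OXT", group_id="peptide", name="C-terminus carboxyl deletion",
        atom_edits=[ModAtomEdit("delete", atom_id="OXT"),
                    ModAtomEdit("delete", atom_id="HXT")])
    nh1 = ModificationEntry(
        id="NH1", group_id="peptide", name="amino-group deprotonation",
        atom_edits=[ModAtomEdit("delete", atom_id="H2")])
    del_hg = ModificationEntry(
        id="DEL-HG", parent_code="CYS", name="thiol hydrogen deletion",
        atom_edits=[ModAtomEdit("delete", atom_id="HG")])
    del_o1 = ModificationEntry(
        id="DEL-O1", group_id="pyranose", name="anomeric hydroxyl deletion",
        atom_edits=[ModAtomEdit("delete", atom_id="O1"),
                    ModAtomEdit("delete", atom_id="HO1")])
    del_ho4 = ModificationEntry(
        id="DEL-HO4", group_id="pyranose", name="O4 hydrogen deletion",
        atom_edits=[ModAtomEdit("delete", atom_id="HO4")])
    return [del_oxt, nh1, del_hg, del_o1, del_ho4]


def _links():
    trans = LinkEntry(
        id="TRANS", name="trans peptide bond",
        group_comp_1="peptide", mod_id_1="DEL-OXT",
        group_comp_2="peptide", mod_id_2="NH1",
        bonds=[LinkBond(1, "C", 2, "N", "single", 1.329, 0.014)],
        angles=[
            LinkAngle(sides=(1, 1, 2), atoms=("CA", "C", "N"),
                      target=116.2, sigma=2.0),
            LinkAngle(sides=(1, 1, 2), atoms=("O", "C", "N"),
                      target=123.0, sigma=1.6),
            LinkAngle(sides=(1, 2, 2), atoms=("C", "N", "CA"),
                      target=121.7, sigma=1.8),
            LinkAngle(sides=(1, 2, 2), atoms=("C", "N", "H"),
                      target=119.2, sigma=3.0)],
        torsions=[LinkTorsion(id="omega", sides=(1, 1, 2, 2),
                              atoms=("CA", "C", "N", "CA"),
                              target=180.0, sigma=5.0, period=1)],
        planes=[LinkPlaneAtom("plan-1", 1, "CA", 0.02),
                LinkPlaneAtom("plan-1", 1, "C", 0.02),
                LinkPlaneAtom("plan-1", 1, "O", 0.02),
                LinkPlaneAtom("plan-1", 2, "N", 0.02),
                LinkPlaneAtom("plan-1", 2, "H", 0.02),
                LinkPlaneAtom("plan-1", 2, "CA", 0.02)])
    ss = LinkEntry(
        id="SS", name="disulfide bridge",
        comp_id_1="CYS", mod_id_1="DEL-HG",
        comp_id_2="CYS", mod_id_2="DEL-HG",
        bonds=[LinkBond(1, "SG", 2, "SG", "single", 2.031, 0.020)],
        angles=[
            LinkAngle(sides=(1, 1, 2), atoms=("CB", "SG", "SG"),
                      target=103.8, sigma=1.8),
            LinkAngle(sides=(1, 2, 2), atoms=("SG", "SG", "CB"),
                      target=103.8, sigma=1.8)],
        torsions=[LinkTorsion(id="chi-ss", sides=(1, 1, 2, 2),
                              atoms=("CB", "SG", "SG", "CB"),
                              target=90.0, sigma=10.0, period=2)])

    def glyco(link_id, sign):
        return LinkEntry(
            id=link_id, name=f"{link_id.lower()} glycosidic bond",
            group_comp_1="pyranose", mod_id_1="DEL-O1",
            group_comp_2="pyranose", mod_id_2="DEL-HO4",
            bonds=[LinkBond(1, "C1", 2, "O4", "single", 1.439, 0.020)],
            angles=[
                LinkAngle(sides=(1, 1, 2), atoms=("O5", "C1", "O4"),
                          target=112.0, sigma=3.0),
                LinkAngle(sides=(1, 1, 2), atoms=("C2", "C1", "O4"),
                          target=109.47, sigma=3.0),
                LinkAngle(sides=(1, 1, 2), atoms=("H1", "C1", "O4"),
                          target=109.47, sigma=3.0),
                LinkAngle(sides=(1, 2, 2), atoms=("C1", "O4", "C4"),
                          target=117.0, sigma=3.0)],
            chirals=[LinkChiral(id="anomeric", centre_side=1, centre="C1",
                                sides=(2, 1, 1), atoms=("O4", "O5", "C2"),
                                sign=sign)])

    # the anomeric configuration: the linking oxygen takes the place of O1,
    # so alpha keeps the free alpha-sugar volume sign and beta flips it
    alpha14 = glyco("ALPHA1-4", "negative")
    beta14 = glyco("BETA1-4", "positive")
    return [trans, ss, alpha14, beta14]


# ---------------------------------------------------------------------------
# public API


def builtin_parameter_table() -> ParameterTable:
    """The shipped parameter table (see data/parameters.json)."""
    return load_parameter_table()


def fragments_cif_text() -> str:
    """The fragment library as shipped package data, in the dictionary CIF
    dialect (it doubles as a format example; reading it back reproduces
    :func:`builtin_fragments` exactly)."""
    from importlib import resources
    return resources.files("linksmith.data").joinpath(
        "fragments.cif").read_text()


def builtin_fragments(complete: bool = True) -> RestraintLibrary:
    """The built-in fragment library: six monomers, five modifications and
    four links, labelled as standard-library entries.

    With ``complete=True`` (default) monomers carry full template
    restraints generated against the built-in parameter table.
    """
    table = builtin_parameter_table()
    lib = RestraintLibrary()
    for build in (_gly, _ala, _cys, _lys, _plp, _glc):
        mon = build()
        if complete:
            mon = complete_description(mon, table)
        lib.monomers[mon.code] = mon
        lib.label("comp", mon.code, "standard")
    for mod in _mods():
        lib.modifications[mod.id] = mod
        lib.label("mod", mod.id, "standard")
    for link in _links():
        lib.links[link.id] = link
        lib.label("link", link.id, "standard")
    return lib


#: the 20 standard amino acids plus common D-forms, for LINK-record surveys
_STANDARD_AMINO = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",
}
_D_AMINO = {"DAL", "DAR", "DSG", "DAS", "DCY", "DGN", "DGL", "DHI", "DIL",
            "DLE", "DLY", "MED", "DPN", "DPR", "DSN", "DTH", "DTR", "DTY",
            "DVA"}


def builtin_amino_codes(include_d: bool = True) -> set:
    codes = set(_STANDARD_AMINO)
    if include_d:
        codes |= _D_AMINO
    return codes


def random_molecule(seed: int, n_heavy: int) -> MonomerDescription:
    """Deterministic random connected molecule over {C, N, O, S}.

    A random tree over the heavy atoms is drawn first (each new atom binds
    a previous atom with free valence), a few eligible bonds are promoted
    to double, and hydrogens fill the remaining valence.
    """
    if not 2 <= n_heavy <= 30:
        raise LinksmithError("n_heavy must be between 2 and 30")
    rng = np.random.default_rng(seed)
    elements = ["C", "N", "O", "S"]
    weights = [0.65, 0.15, 0.15, 0.05]
    desc = MonomerDescription(code="RND", name=f"random molecule {seed}",
                              level="minimal")
    counts = {}

    def new_atom():
        el = rng.choice(elements, p=weights)
        counts[el] = counts.get(el, 0) + 1
        name = f"{el}{counts[el]}"
        atom = AtomSpec(name, el, parent_ref=name)
        desc.add_atom(atom)
        return name

    def free(name):
        atom = desc.atoms[name]
        return (effective_valence(atom.element)
                - int(desc.bond_order_sum(name)))

    new_atom()
    while len(desc.atoms) < n_heavy:
        # a tree always leaves free valence somewhere (sum v > 2 (n-1))
        hosts = [n for n in desc.atoms if free(n) >= 1]
        host = hosts[int(rng.integers(len(hosts)))]
        name = new_atom()
        desc.add_bond(BondSpec(host, name, "single"))

    for bond in desc.bonds:
        if (free(bond.atom1) >= 1 and free(bond.atom2) >= 1
                and rng.random() < 0.25):
            bond.order = "double"

    desc, _ = adjust_hydrogens(desc)
    desc.journal.clear()
    for atom in desc.atoms.values():
        atom.parent_ref = atom.name
    return desc


# ---------------------------------------------------------------------------
# library-design combinatorics


@dataclass
class DesignScheme:
    """How a polymer library is laid out: one entry per monomer variant
    (``monomer_only``) versus shared monomers plus generic modifications
    and links (``link_mod``)."""

    scheme: str  # monomer_only | link_mod
    n_monomers: int
    positions: int = 1       # chain contexts (N-terminal/internal/C-terminal)
    conformations: int = 1   # e.g. cis/trans
    n_generic_mods: int = 0
    n_generic_links: int = 0

    def __post_init__(self):
        if self.scheme not in ("monomer_only", "link_mod"):
            raise LinksmithError(f"unknown scheme {self.scheme!r}")
        if min(self.n_monomers, self.positions, self.conformations,
               self.n_generic_mods, self.n_generic_links) < 0:
            raise LinksmithError("design-scheme counts must be >= 0")
        if self.positions * self.conformations < 1:
            raise LinksmithError("positions x conformations must be >= 1")


def count_design_entries(ds: DesignScheme) -> int:
    """Number of library entries the scheme needs.

    Monomer-only libraries replicate every monomer for each position and
    conformation; the link/modification scheme stores each monomer once
    plus the shared generic entries.
    """
    if ds.scheme == "monomer_only":
        return ds.n_monomers * ds.positions * ds.conformations
    return ds.n_monomers + ds.n_generic_mods + ds.n_generic_links
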