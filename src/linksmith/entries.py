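"""Modification and link entries.

A modification records add/delete/change edits against a named parent
monomer; a link records the cross-monomer restraints (with a side
discriminator per atom) that join two, possibly modified, monomers.
Both are pure data; the algorithms that produce and consume them live in
:mod:`linksmith.linkgen`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

FUNCTIONS = ("add", "delete", "change")


@dataclass
class ModAtomEdit:
    function: str
    atom_id: Optional[str] = None        # existing atom (delete/change)
    new_atom_id: Optional[str] = None    # added atom, or rename target
    new_element: Optional[str] = None
    new_energy_type: Optional[str] = None
    new_charge: Optional[int] = None


@dataclass
class ModBondEdit:
    function: str
    atom1: str
    atom2: str
    new_order: Optional[str] = None
    new_target: Optional[float] = None
    new_sigma: Optional[float] = None


@dataclass
class ModAngleEdit:
    function: str
    atom1: str
    atom2: str
    atom3: str
    new_target: Optional[float] = None
    new_sigma: Optional[float] = None


@dataclass
class ModTorsionEdit:
    function: str
    id: str
    atoms: tuple = ()
    new_target: Optional[float] = None
    new_sigma: Optional[float] = None
    new_period: Optional[int] = None


@dataclass
class ModChiralEdit:
    function: str
    id: str
    centre: Optional[str] = None
    atoms: tuple = ()
    new_sign: Optional[str] = None


@dataclass
class ModPlaneAtomEdit:
    """Plane groups are edited per atom row; a ``delete`` row whose
    ``atom_id`` is None removes the whole group."""

    function: str
    plane_id: str
    atom_id: Optional[str] = None
    new_sigma: Optional[float] = None


@dataclass
class ModificationEntry:
    id: str
    parent_code: str = ""        # comp the mod applies to; "" for generic
    group_id: str = ""           # monomer group for generic mods
    name: str = ""
    atom_edits: list = field(default_factory=list)
    bond_edits: list = field(default_factory=list)
    angle_edits: list = field(default_factory=list)
    torsion_edits: list = field(default_factory=list)
    chiral_edits: list = field(default_factory=list)
    plane_edits: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def is_empty(self) -> bool:
        return not any((self.atom_edits, self.bond_edits, self.angle_edits,
                        self.torsion_edits, self.chiral_edits,
                        self.plane_edits))


@dataclass
class LinkBond:
    side1: int
    atom1: str
    side2: int
    atom2: str
    order: str = "single"
    target: Optional[float] = None
    sigma: Optional[float] = None


@dataclass
class LinkAngle:
    sides: tuple  # 3 ints in {1, 2}
    atoms: tuple
    target: Optional[float] = None
    sigma: Optional[float] = None


@dataclass
class LinkTorsion:
    id: str
    sides: tuple
    atoms: tuple
    target: Optional[float] = None
    sigma: Optional[float] = None
    period: int = 1


@dataclass
class LinkChiral:
    id: str
    centre_side: int
    centre: str
    sides: tuple
    atoms: tuple
    sign: str = "both"


@dataclass
class LinkPlaneAtom:
    plane_id: str
    side: int
    atom: str
    sigma: float = 0.02


@dataclass
class LinkEntry:
    id: str
    name: str = ""
    comp_id_1: str = ""      # specific comp code, or "" when generic
    mod_id_1: str = ""
    group_comp_1: str = ""   # group constraint when generic from side 1
    comp_id_2: str = ""
    mod_id_2: str = ""
    group_comp_2: str = ""
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    torsions: list = field(default_factory=list)
    chirals: list = field(default_factory=list)
    planes: list = field(default_factory=list)  # LinkPlaneAtom rows
    extra: dict = field(default_factory=dict)

    def crosses_sides(self) -> bool:
        """At least one bond must join the two sides."""
        return any(b.side1 != b.side2 for b in self.bonds)
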