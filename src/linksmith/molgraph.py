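"""Molecular-graph model for restraint dictionaries.

A :class:`MonomerDescription` is the in-memory form of one dictionary entry:
the molecular graph (atoms, bonds with orders) plus the template restraints
(angles, torsions, chiral centres, planar groups).  Two description levels
exist: *minimal* (graph, names and chirality only) and *complete* (every
bond/angle carries a target value and an uncertainty, and planar groups are
listed).

Editing goes through :func:`apply_edit` so that every change is journalled;
each surviving atom keeps a ``parent_ref`` to the atom it descends from in
the pre-edit monomer, which is what later allows a composite compound to be
diffed back into modification entries.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .errors import EditError, ValenceError

__all__ = [
    "AtomSpec",
    "BondSpec",
    "AngleRestraint",
    "TorsionRestraint",
    "ChiralCenter",
    "PlaneGroup",
    "MonomerDescription",
    "GraphEdit",
    "Finding",
    "apply_edit",
    "replay_journal",
    "adjust_hydrogens",
    "chiral_volume",
    "chirality_sign",
    "validate",
    "effective_valence",
    "hydrogen_name",
]

BOND_ORDERS = ("single", "double", "triple", "aromatic", "deloc")

#: contribution of each bond order towards valence; aromatic/delocalized
#: bonds count 1.5 and the per-atom sum is floored before hydrogen counting
ORDER_VALUE = {
    "single": 1.0,
    "double": 2.0,
    "triple": 3.0,
    "aromatic": 1.5,
    "deloc": 1.5,
}

#: standard valences for the elements the fixtures use; extensible
STANDARD_VALENCE = {
    "H": 1,
    "C": 4,
    "N": 3,
    "O": 2,
    "P": 5,
    "S": 2,
    "SE": 2,
    "F": 1,
    "CL": 1,
    "BR": 1,
    "I": 1,
}

#: elements recognised as existing at all (superset of the valence table)
KNOWN_ELEMENTS = set(STANDARD_VALENCE) | {
    "B", "SI", "AS", "LI", "NA", "K", "MG", "CA", "MN", "FE", "CO", "NI",
    "CU", "ZN",
}

#: margin below which a chiral volume is called degenerate rather than signed
CHIRAL_DEGENERATE_MARGIN = 0.1  # A^3


def effective_valence(element: str, charge: int = 0) -> int:
    """Valence available for bonding: standard valence shifted by the formal
    charge (N+ binds 4, O- binds 1, thiolate S- binds 1, carbanion C- 3)."""
    std = STANDARD_VALENCE.get(element.upper())
    if std is None:
        raise ValenceError(f"element {element!r} not in valence table")
    return std + charge


@dataclass
class AtomSpec:
    """One atom of a monomer.

    ``parent_ref`` names the atom of the pre-edit monomer this atom descends
    from; it is ``None`` exactly when the atom was added during editing.
    """

    name: str
    element: str
    energy_type: Optional[str] = None
    charge: int = 0
    parent_ref: Optional[str] = None

    def __post_init__(self):
        if not self.name or len(self.name) > 4:
            raise EditError(f"atom name {self.name!r} must be 1-4 characters")
        if self.element.upper() not in KNOWN_ELEMENTS:
            raise EditError(f"unknown element {self.element!r} for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class BondSpec:
    atom1: str
    atom2: str
    order: str = "single"
    target: Optional[float] = None  # Angstrom; unset at minimal level
    sigma: Optional[float] = None

    def __post_init__(self):
        if self.atom1 == self.atom2:
            raise EditError(f"bond from atom {self.atom1!r} to itself")
        if self.order not in BOND_ORDERS:
            raise EditError(f"unknown bond order {self.order!r}")

    @property
    def key(self) -> frozenset:
        return frozenset((self.atom1, self.atom2))


@dataclass
class AngleRestraint:
    atom1: str
    atom2: str  # vertex
    atom3: str
    target: Optional[float] = None  # degrees
    sigma: Optional[float] = None

    @property
    def key(self):
        a, c = sorted((self.atom1, self.atom3))
        return (a, self.atom2, c)


@dataclass
class TorsionRestraint:
    id: str
    atom1: str
    atom2: str
    atom3: str
    atom4: str
    target: Optional[float] = None  # degrees
    sigma: Optional[float] = None
    period: int = 1

    @property
    def atoms(self):
        return (self.atom1, self.atom2, self.atom3, self.atom4)

    @property
    def key(self):
        fwd = self.atoms
        rev = fwd[::-1]
        return min(fwd, rev)


@dataclass
class ChiralCenter:
    id: str
    centre: str
    atom1: str
    atom2: str
    atom3: str
    sign: str = "both"  # positive | negative | both

    def __post_init__(self):
        if self.sign not in ("positive", "negative", "both"):
            raise EditError(f"chirality sign {self.sign!r} invalid")

    @property
    def neighbours(self):
        return (self.atom1, self.atom2, self.atom3)


@dataclass
class PlaneGroup:
    id: str
    atoms: list  # atom names, >= 3
    sigma: float = 0.02  # A, distance esd applied to every member
    # per-atom override (name -> esd); rarely used, kept for dialect fidelity
    atom_sigmas: dict = field(default_factory=dict)

    def sigma_for(self, name: str) -> float:
        return self.atom_sigmas.get(name, self.sigma)


@dataclass
class GraphEdit:
    """A journalled edit. ``kind`` selects which payload keys are read."""

    kind: str
    payload: dict = field(default_factory=dict)

    KINDS = (
        "add_atom", "delete_atom", "add_bond", "delete_bond",
        "change_bond", "change_atom", "set_chirality",
    )

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise EditError(f"unknown edit kind {self.kind!r}")


@dataclass
class Finding:
    kind: str
    message: str


@dataclass
class MonomerDescription:
    """Molecular graph plus template restraints for one compound."""

    code: str
    name: str = ""
    group: str = "non-polymer"
    level: str = "minimal"  # minimal | complete
    atoms: dict = field(default_factory=dict)  # name -> AtomSpec, ordered
    bonds: list = field(default_factory=list)  # BondSpec
    angles: list = field(default_factory=list)
    torsions: list = field(default_factory=list)
    chirals: list = field(default_factory=list)
    planes: list = field(default_factory=list)
    journal: list = field(default_factory=list)  # GraphEdit, append-only
    extra: dict = field(default_factory=dict)  # unknown CIF payload, opaque

    # -- construction helpers ------------------------------------------------

    def add_atom(self, atom: AtomSpec) -> None:
        if atom.name in self.atoms:
            raise EditError(f"duplicate atom name {atom.name!r} in {self.code}")
        self.atoms[atom.name] = atom

    def add_bond(self, bond: BondSpec) -> None:
        for n in (bond.atom1, bond.atom2):
            if n not in self.atoms:
                raise EditError(f"bond references unknown atom {n!r}")
        if self.bond_between(bond.atom1, bond.atom2) is not None:
            raise EditError(
                f"duplicate bond {bond.atom1}-{bond.atom2} in {self.code}")
        self.bonds.append(bond)

    # -- queries -------------------------------------------------------------

    def bond_between(self, a: str, b: str) -> Optional[BondSpec]:
        key = frozenset((a, b))
        for bond in self.bonds:
            if bond.key == key:
                return bond
        return None

    def neighbours(self, name: str) -> list:
        out = []
        for bond in self.bonds:
            if bond.atom1 == name:
                out.append(bond.atom2)
            elif bond.atom2 == name:
                out.append(bond.atom1)
        return out

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms.values() if not a.is_hydrogen]

    def hydrogens_on(self, name: str) -> list:
        return [n for n in self.neighbours(name) if self.atoms[n].is_hydrogen]

    def bond_order_sum(self, name: str, heavy_only: bool = False) -> float:
        total = 0.0
        for bond in self.bonds:
            other = None
            if bond.atom1 == name:
                other = bond.atom2
            elif bond.atom2 == name:
                other = bond.atom1
            if other is None:
                continue
            if heavy_only and self.atoms[other].is_hydrogen:
                continue
            total += ORDER_VALUE[bond.order]
        return total

    def copy(self) -> "MonomerDescription":
        return copy.deepcopy(self)

    # -- restraint bookkeeping ----------------------------------------------

    def drop_restraints_of(self, name: str) -> None:
        """Remove every restraint that references ``name``."""
        self.angles = [a for a in self.angles
                       if name not in (a.atom1, a.atom2, a.atom3)]
        self.torsions = [t for t in self.torsions if name not in t.atoms]
        self.chirals = [c for c in self.chirals
                        if name != c.centre and name not in c.neighbours]
        for plane in self.planes:
            if name in plane.atoms:
                plane.atoms = [a for a in plane.atoms if a != name]
                plane.atom_sigmas.pop(name, None)
        self.planes = [p for p in self.planes if len(p.atoms) >= 3]

    def rename_atom(self, old: str, new: str) -> None:
        if old not in self.atoms:
            raise EditError(f"cannot rename unknown atom {old!r}")
        if new != old and new in self.atoms:
            raise EditError(f"rename target {new!r} already exists")
        atom = self.atoms.pop(old)
        atom.name = new
        # rebuild to keep insertion order stable
        rebuilt = {}
        inserted = False
        for k, v in self.atoms.items():
            rebuilt[k] = v
        rebuilt[new] = atom
        self.atoms = rebuilt
        for bond in self.bonds:
            if bond.atom1 == old:
                bond.atom1 = new
            if bond.atom2 == old:
                bond.atom2 = new
        for ang in self.angles:
            for f in ("atom1", "atom2", "atom3"):
                if getattr(ang, f) == old:
                    setattr(ang, f, new)
        for tor in self.torsions:
            for f in ("atom1", "atom2", "atom3", "atom4"):
                if getattr(tor, f) == old:
                    setattr(tor, f, new)
        for ch in self.chirals:
            for f in ("centre", "atom1", "atom2", "atom3"):
                if getattr(ch, f) == old:
                    setattr(ch, f, new)
        for plane in self.planes:
            plane.atoms = [new if a == old else a for a in plane.atoms]
            if old in plane.atom_sigmas:
                plane.atom_sigmas[new] = plane.atom_sigmas.pop(old)
        _ = inserted


# ---------------------------------------------------------------------------
# editing


def apply_edit(desc: MonomerDescription, edit: GraphEdit) -> MonomerDescription:
    """Return a copy of ``desc`` with one edit applied and journalled.

    Deleting an atom removes all of its bonds and every restraint that
    mentions it.  Atoms added here carry no ``parent_ref``.
    """
    out = desc.copy()
    p = edit.payload
    if edit.kind == "add_atom":
        atom = p["atom"]
        spec = replace(atom, parent_ref=None) if isinstance(atom, AtomSpec) else AtomSpec(**atom)
        spec.parent_ref = None
        out.add_atom(spec)
    elif edit.kind == "delete_atom":
        name = p["name"]
        if name not in out.atoms:
            raise EditError(f"cannot delete unknown atom {name!r}")
        del out.atoms[name]
        out.bonds = [b for b in out.bonds if name not in (b.atom1, b.atom2)]
        out.drop_restraints_of(name)
    elif edit.kind == "add_bond":
        out.add_bond(BondSpec(p["atom1"], p["atom2"], p.get("order", "single")))
    elif edit.kind == "delete_bond":
        bond = out.bond_between(p["atom1"], p["atom2"])
        if bond is None:
            raise EditError(f"no bond {p['atom1']}-{p['atom2']} to delete")
        out.bonds.remove(bond)
    elif edit.kind == "change_bond":
        bond = out.bond_between(p["atom1"], p["atom2"])
        if bond is None:
            raise EditError(f"no bond {p['atom1']}-{p['atom2']} to change")
        bond.order = p["order"]
        if "target" in p:
            bond.target = p["target"]
        if "sigma" in p:
            bond.sigma = p["sigma"]
    elif edit.kind == "change_atom":
        name = p["name"]
        if name not in out.atoms:
            raise EditError(f"cannot change unknown atom {name!r}")
        atom = out.atoms[name]
        if "element" in p:
            atom.element = p["element"]
        if "energy_type" in p:
            atom.energy_type = p["energy_type"]
        if "charge" in p:
            atom.charge = p["charge"]
        if p.get("new_name") and p["new_name"] != name:
            out.rename_atom(name, p["new_name"])
    elif edit.kind == "set_chirality":
        centre = p["centre"]
        if centre not in out.atoms:
            raise EditError(f"no atom {centre!r} for chirality change")
        for ch in out.chirals:
            if ch.centre == centre:
                ch.sign = p["sign"]
                break
        else:
            nbrs = p.get("neighbours")
            if not nbrs:
                raise EditError(f"atom {centre!r} has no chiral record and no "
                                "neighbours were given")
            out.chirals.append(ChiralCenter(
                id=f"chir_{len(out.chirals) + 1}", centre=centre,
                atom1=nbrs[0], atom2=nbrs[1], atom3=nbrs[2], sign=p["sign"]))
    out.journal.append(edit)
    return out


def replay_journal(original: MonomerDescription,
                   journal: Iterable[GraphEdit]) -> MonomerDescription:
    """Re-apply a journal to the pre-edit monomer (diff soundness oracle)."""
    desc = original
    for edit in journal:
        desc = apply_edit(desc, edit)
    return desc


# ---------------------------------------------------------------------------
# hydrogens


def hydrogen_name(parent: str, element: str, taken: set) -> str:
    """Name a new H from its heavy parent: NZ -> HZ1, HZ2, ...

    The suffix is the parent name with its leading element symbol stripped;
    a counter guarantees uniqueness within 4 characters.
    """
    suffix = parent[len(element):] if parent.upper().startswith(element.upper()) else parent
    base = ("H" + suffix)[:3]
    i = 1
    while True:
        cand = f"{base}{i}"
        if len(cand) > 4:
            base = base[:4 - len(str(i))]
            cand = f"{base}{i}"
        if cand not in taken:
            return cand
        i += 1


def adjust_hydrogens(desc: MonomerDescription):
    """Bring every heavy atom to its valence-implied hydrogen count.

    The target count is ``effective_valence - floor(sum of heavy bond
    orders)`` (aromatic/delocalized bonds count 1.5 each).  Orphaned H atoms
    (left behind by a heavy-atom deletion) are removed first.  Returns the
    adjusted description and exactly the list of automatic edits applied;
    the edits are also journalled.  Idempotent.
    """
    out = desc
    edits = []

    def record(edit):
        nonlocal out
        out = apply_edit(out, edit)
        edits.append(edit)

    # orphan hydrogens: H bonded to no heavy atom
    for atom in list(desc.atoms.values()):
        if atom.is_hydrogen:
            heavies = [n for n in desc.neighbours(atom.name)
                       if not desc.atoms[n].is_hydrogen]
            if not heavies:
                record(GraphEdit("delete_atom", {"name": atom.name}))

    for atom in list(out.atoms.values()):
        if atom.name not in out.atoms or atom.is_hydrogen:
            continue
        val = effective_valence(atom.element, atom.charge)
        heavy = math.floor(out.bond_order_sum(atom.name, heavy_only=True) + 1e-9)
        if heavy > val:
            err = ValenceError(
                f"atom {atom.name} ({atom.element}, charge {atom.charge:+d}) "
                f"carries bond order {heavy} exceeding valence {val}")
            err.atom = atom.name
            raise err
        want = val - heavy
        have = out.hydrogens_on(atom.name)
        if len(have) > want:
            # drop the highest-sorting surplus hydrogens, deterministically
            for h in sorted(have)[want:]:
                record(GraphEdit("delete_atom", {"name": h}))
        elif len(have) < want:
            for _ in range(want - len(have)):
                taken = set(out.atoms)
                hname = hydrogen_name(atom.name, atom.element, taken)
                record(GraphEdit("add_atom",
                                 {"atom": AtomSpec(hname, "H")}))
                record(GraphEdit("add_bond",
                                 {"atom1": atom.name, "atom2": hname,
                                  "order": "single"}))
    return out, edits


# ---------------------------------------------------------------------------
# chirality


def chiral_volume(centre, n1, n2, n3) -> float:
    """Signed volume det[v1 v2 v3], vi = neighbour_i - centre (A^3).

    The sign encodes handedness; swapping two neighbours flips it.
    """
    c = np.asarray(centre, dtype=float)
    m = np.stack([np.asarray(n, dtype=float) - c for n in (n1, n2, n3)])
    return float(np.linalg.det(m))


def chirality_sign(volume: float) -> str:
    """Classify a signed volume: beyond +-0.1 A^3 it is positive/negative,
    inside that margin the geometry is flagged degenerate."""
    if volume > CHIRAL_DEGENERATE_MARGIN:
        return "positive"
    if volume < -CHIRAL_DEGENERATE_MARGIN:
        return "negative"
    return "degenerate"


# ---------------------------------------------------------------------------
# validation


def validate(desc: MonomerDescription) -> list:
    """Report-only integrity check; an empty report means the description
    satisfies the graph invariants."""
    findings = []
    # the container is keyed by name, but a mis-keyed entry can still smuggle
    # in a duplicate printed name; count the names the atoms themselves carry
    seen = set()
    for atom in desc.atoms.values():
        if atom.name in seen:
            findings.append(Finding("duplicate-name",
                                    f"duplicate atom name {atom.name}"))
        seen.add(atom.name)

    def check_ref(ref, where):
        if ref not in desc.atoms:
            findings.append(Finding("dangling-reference",
                                    f"{where} references unknown atom {ref}"))

    pair_seen = set()
    for bond in desc.bonds:
        check_ref(bond.atom1, f"bond {bond.atom1}-{bond.atom2}")
        check_ref(bond.atom2, f"bond {bond.atom1}-{bond.atom2}")
        if bond.key in pair_seen:
            findings.append(Finding("duplicate-bond",
                                    f"duplicate bond {bond.atom1}-{bond.atom2}"))
        pair_seen.add(bond.key)
    for ang in desc.angles:
        for ref in (ang.atom1, ang.atom2, ang.atom3):
            check_ref(ref, f"angle {ang.atom1}-{ang.atom2}-{ang.atom3}")
        if (ang.atom1 in desc.atoms and ang.atom2 in desc.atoms
                and ang.atom1 not in desc.neighbours(ang.atom2)):
            findings.append(Finding("angle-topology",
                                    f"angle endpoint {ang.atom1} not bonded to vertex {ang.atom2}"))
        if (ang.atom3 in desc.atoms and ang.atom2 in desc.atoms
                and ang.atom3 not in desc.neighbours(ang.atom2)):
            findings.append(Finding("angle-topology",
                                    f"angle endpoint {ang.atom3} not bonded to vertex {ang.atom2}"))
    for tor in desc.torsions:
        for ref in tor.atoms:
            check_ref(ref, f"torsion {tor.id}")
        for a, b in zip(tor.atoms, tor.atoms[1:]):
            if a in desc.atoms and b in desc.atoms and desc.bond_between(a, b) is None:
                findings.append(Finding("torsion-topology",
                                        f"torsion {tor.id}: {a} and {b} not bonded"))
    for ch in desc.chirals:
        check_ref(ch.centre, f"chiral centre {ch.id}")
        for ref in ch.neighbours:
            check_ref(ref, f"chiral centre {ch.id}")
            if (ref in desc.atoms and ch.centre in desc.atoms
                    and desc.bond_between(ch.centre, ref) is None):
                findings.append(Finding("chirality-topology",
                                        f"chiral {ch.id}: {ref} not bonded to centre {ch.centre}"))
    for plane in desc.planes:
        if len(plane.atoms) < 3:
            findings.append(Finding("plane-size",
                                    f"plane {plane.id} has fewer than 3 atoms"))
        for ref in plane.atoms:
            check_ref(ref, f"plane {plane.id}")

    # connectivity
    if len(desc.atoms) > 1:
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(desc.atoms)
        g.add_edges_from((b.atom1, b.atom2) for b in desc.bonds
                         if b.atom1 in desc.atoms and b.atom2 in desc.atoms)
        ncomp = nx.number_connected_components(g)
        if ncomp > 1:
            findings.append(Finding("disconnected",
                                    f"graph has {ncomp} connected fragments"))

    # valence
    for atom in desc.atoms.values():
        try:
            val = effective_valence(atom.element, atom.charge)
        except ValenceError:
            findings.append(Finding("valence", f"atom {atom.name}: element "
                                    f"{atom.element} not in valence table"))
            continue
        total = math.floor(desc.bond_order_sum(atom.name) + 1e-9)
        if total > val:
            findings.append(Finding("valence",
                                    f"atom {atom.name} has bond order {total} > valence {val}"))
    return findings
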