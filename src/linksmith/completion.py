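"""From minimal to complete descriptions, and back from coordinates.

A *minimal* description carries the molecular graph, atom names and
chirality types.  Completing it means (i) assigning every atom an energy
type from its element, hybridization, hydrogen count and ring membership,
(ii) enumerating the template restraints implied by the graph -- one angle
per bonded path of length two, one torsion per central bond, chiral centres
at stereogenic tetravalent atoms, planar groups around sp2 centres -- and
(iii) looking up target values and sigmas in a parameter table keyed by
energy types, with element-pair and covalent-radii fallbacks.

The reverse direction starts from coordinates: :func:`perceive_graph`
recovers the graph from interatomic distances and covalent radii, and
:func:`targets_from_coordinates` copies observed geometry into the restraint
targets (the "as-is" mode, intended for high-precision input coordinates).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import networkx as nx
import numpy as np

from . import geometry
from .errors import CoordinateError, ValenceError
from .molgraph import (
    AngleRestraint,
    AtomSpec,
    BondSpec,
    ChiralCenter,
    MonomerDescription,
    PlaneGroup,
    TorsionRestraint,
    chiral_volume,
    chirality_sign,
    effective_valence,
)

#: slack added to the covalent-radii sum when perceiving bonds from coordinates
BOND_PERCEPTION_TOLERANCE = 0.45  # A
#: two atoms closer than this are rejected as overlapping
OVERLAP_LIMIT = 0.5  # A

_ATOMIC_NUMBER = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12,
    "SI": 14, "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25,
    "FE": 26, "CO": 27, "NI": 28, "CU": 29, "ZN": 30, "SE": 34, "BR": 35,
    "I": 53,
}


def atomic_number(element: str) -> int:
    return _ATOMIC_NUMBER.get(element.upper(), 0)


# ---------------------------------------------------------------------------
# parameter table


@dataclass
class ParameterTable:
    """Atom-energy-type keyed targets for bonds and angles.

    Lookup falls through three levels: exact typed entry, element-pair entry,
    and finally a covalent-radii / hybridization default.  Every fallback
    use is recorded in :attr:`fallback_log`.
    """

    typed_bonds: dict = field(default_factory=dict)
    typed_angles: dict = field(default_factory=dict)
    element_bonds: dict = field(default_factory=dict)
    covalent_radii: dict = field(default_factory=dict)
    defaults: dict = field(default_factory=dict)
    fallback_log: list = field(default_factory=list)

    # -- keys are symmetric under reversal ----------------------------------

    @staticmethod
    def _bond_key(t1, t2, order):
        a, b = sorted((t1, t2))
        return (a, b, order)

    @staticmethod
    def _angle_key(t1, t2, t3):
        a, c = sorted((t1, t3))
        return (a, t2, c)

    def radius(self, element: str) -> float:
        try:
            return self.covalent_radii[element.upper()]
        except KeyError:
            raise ValenceError(f"no covalent radius for element {element!r}")

    def bond(self, type1: str, type2: str, order: str,
             elem1: Optional[str] = None, elem2: Optional[str] = None):
        """(target A, sigma A) for a bond between two energy types."""
        hit = self.typed_bonds.get(self._bond_key(type1 or "", type2 or "", order))
        if hit is not None:
            return tuple(hit)
        e1 = (elem1 or _type_element(type1)).upper()
        e2 = (elem2 or _type_element(type2)).upper()
        hit = self.element_bonds.get(self._bond_key(e1, e2, order))
        if hit is not None:
            return tuple(hit)
        # element pair of another order, scaled crudely via radii? no:
        # radii-sum global default
        length = self.radius(e1) + self.radius(e2)
        if order == "double":
            length -= 0.12
        elif order == "triple":
            length -= 0.22
        elif order in ("aromatic", "deloc"):
            length -= 0.06
        sigma = self.defaults.get("fallback_bond_sigma", 0.03)
        self.fallback_log.append(("bond", type1, type2, order, round(length, 3)))
        return (round(length, 3), sigma)

    def angle(self, type1: str, type2: str, type3: str, default: float):
        """(target deg, sigma deg); ``default`` is the hybridization ideal
        used when no typed entry exists."""
        hit = self.typed_angles.get(self._angle_key(type1 or "", type2 or "", type3 or ""))
        if hit is not None:
            return tuple(hit)
        return (default, self.defaults.get("angle_sigma", 3.0))


def load_parameter_table() -> ParameterTable:
    """The shipped parameter table (Engh & Huber-style peptide values plus
    element-pair fallbacks covering the fragment set)."""
    raw = json.loads(
        resources.files("linksmith.data").joinpath("parameters.json").read_text())

    def unkey(d):
        return {ParameterTable._bond_key(*k.split("|")): tuple(v)
                for k, v in d.items()}

    angles = {ParameterTable._angle_key(*k.split("|")): tuple(v)
              for k, v in raw["typed_angles"].items()}
    return ParameterTable(
        typed_bonds=unkey(raw["typed_bonds"]),
        typed_angles=angles,
        element_bonds=unkey(raw["element_bonds"]),
        covalent_radii=raw["covalent_radii"],
        defaults=raw["defaults"],
    )


def _type_element(energy_type: Optional[str]) -> str:
    """Element encoded in an energy-type string (e.g. 'C3h2' -> 'C',
    'SE3' -> 'SE')."""
    if not energy_type:
        return ""
    sym = "".join(ch for ch in energy_type if ch.isalpha() and ch.isupper())
    return sym or energy_type[0].upper()


# ---------------------------------------------------------------------------
# hybridization and energy typing


def ring_atoms(desc: MonomerDescription) -> set:
    g = nx.Graph()
    g.add_nodes_from(desc.atoms)
    g.add_edges_from((b.atom1, b.atom2) for b in desc.bonds)
    out = set()
    for cycle in nx.cycle_basis(g):
        out.update(cycle)
    return out


def hybridization(desc: MonomerDescription, name: str) -> int:
    """1 (sp), 2 (sp2) or 3 (sp3) from bond orders.

    A nitrogen with only single bonds is still typed sp2 when it sits next
    to a carbon bearing a double bond to O or S (amide resonance)."""
    orders = []
    for bond in desc.bonds:
        if name in (bond.atom1, bond.atom2):
            orders.append(bond.order)
    if "triple" in orders or orders.count("double") >= 2:
        return 1
    if any(o in ("double", "aromatic", "deloc") for o in orders):
        return 2
    atom = desc.atoms[name]
    if atom.element.upper() == "N":
        for nbr in desc.neighbours(name):
            if desc.atoms[nbr].element.upper() != "C":
                continue
            for bond in desc.bonds:
                if nbr not in (bond.atom1, bond.atom2) or bond.order != "double":
                    continue
                other = bond.atom2 if bond.atom1 == nbr else bond.atom1
                if desc.atoms[other].element.upper() in ("O", "S"):
                    return 2
    return 3


def energy_type_of(desc: MonomerDescription, name: str, rings: set) -> str:
    atom = desc.atoms[name]
    el = atom.element.upper()
    if el == "H":
        return "H"
    if el not in _ATOMIC_NUMBER or el not in ("C", "N", "O", "P", "S", "SE",
                                              "F", "CL", "BR", "I", "B"):
        # still typed, table will fall back by element
        pass
    try:
        effective_valence(el)
    except ValenceError as exc:
        raise ValenceError(f"cannot type atom {name}: {exc}") from exc
    t = f"{el}{hybridization(desc, name)}"
    if name in rings:
        t += "r"
    n_h = len(desc.hydrogens_on(name))
    if n_h:
        t += f"h{n_h}"
    return t


def assign_energy_types(desc: MonomerDescription) -> MonomerDescription:
    """Deterministically type every atom from its chemical environment."""
    out = desc.copy()
    rings = ring_atoms(out)
    for name in out.atoms:
        out.atoms[name].energy_type = energy_type_of(out, name, rings)
    return out


def ideal_angle(desc: MonomerDescription, vertex: str, defaults: dict) -> float:
    """Hybridization/steric ideal for the angle at ``vertex``."""
    n = len(desc.neighbours(vertex))
    hyb = hybridization(desc, vertex)
    if n >= 4:
        return defaults.get("tetrahedral_angle", 109.47)
    if hyb == 1:
        return defaults.get("linear_angle", 180.0)
    if hyb == 2:
        return defaults.get("trigonal_angle", 120.0)
    return defaults.get("tetrahedral_angle", 109.47)


# ---------------------------------------------------------------------------
# restraint enumeration


def _neighbour_rank(desc: MonomerDescription, name: str):
    return (-atomic_number(desc.atoms[name].element), name)


def enumerate_angles(desc: MonomerDescription) -> list:
    """One angle per bonded path of length two, canonically ordered."""
    out = []
    for vertex in sorted(desc.atoms):
        nbrs = sorted(desc.neighbours(vertex))
        for a, c in itertools.combinations(nbrs, 2):
            out.append((a, vertex, c))
    return out


def enumerate_torsions(desc: MonomerDescription) -> list:
    """One torsion per central bond with both ends non-terminal.

    End atoms are the highest-priority neighbours (atomic number, then
    name) so the choice does not depend on insertion order.
    """
    out = []
    for bond in sorted(desc.bonds, key=lambda b: tuple(sorted((b.atom1, b.atom2)))):
        b, c = sorted((bond.atom1, bond.atom2))
        ends_b = [n for n in desc.neighbours(b) if n != c]
        ends_c = [n for n in desc.neighbours(c) if n != b]
        if not ends_b or not ends_c:
            continue
        a = min(ends_b, key=lambda n: _neighbour_rank(desc, n))
        d = min(ends_c, key=lambda n: _neighbour_rank(desc, n))
        out.append((a, b, c, d))
    return out


def _substituent_signature(desc: MonomerDescription, name: str):
    elems = sorted(desc.atoms[n].element.upper() for n in desc.neighbours(name))
    return (desc.atoms[name].element.upper(), tuple(elems))


def detect_chiral_centres(desc: MonomerDescription) -> list:
    """Tetravalent atoms with at least three distinguishable heavy
    substituents.  Distinguishability uses a one-shell signature (element
    plus sorted neighbour elements), deliberately local."""
    declared = {c.centre for c in desc.chirals}
    found = []
    for name in sorted(desc.atoms):
        if name in declared:
            continue
        nbrs = desc.neighbours(name)
        if len(nbrs) != 4:
            continue
        heavy = [n for n in nbrs if not desc.atoms[n].is_hydrogen]
        if len(heavy) < 3:
            continue
        sigs = {_substituent_signature(desc, n) for n in heavy}
        if len(sigs) >= 3:
            ordered = sorted(heavy, key=lambda n: _neighbour_rank(desc, n))[:3]
            found.append((name, tuple(ordered)))
    return found


def enumerate_planes(desc: MonomerDescription, defaults: dict) -> list:
    """Planar groups: each trigonal sp2 atom with its bonded neighbours,
    merged while two groups share at least two atoms.  Four-coordinate
    atoms (e.g. phosphate P) are tetrahedral regardless of bond orders and
    never seed a plane."""
    groups = []
    for name in sorted(desc.atoms):
        if desc.atoms[name].is_hydrogen:
            continue
        nbrs = desc.neighbours(name)
        if hybridization(desc, name) == 2 and 2 <= len(nbrs) <= 3:
            groups.append(set([name] + nbrs))
    merged = True
    while merged:
        merged = False
        for i, j in itertools.combinations(range(len(groups)), 2):
            if len(groups[i] & groups[j]) >= 2:
                groups[i] |= groups[j]
                del groups[j]
                merged = True
                break
    sigma = defaults.get("plane_sigma", 0.02)
    groups = [sorted(g) for g in groups if len(g) >= 3]
    groups.sort(key=lambda g: g[0])
    return [PlaneGroup(id=f"plan-{i + 1}", atoms=g, sigma=sigma)
            for i, g in enumerate(groups)]


def _apply_planar_ring_angles(desc: MonomerDescription) -> None:
    """Make planar-ring angle targets consistent with the ring's bond
    targets.

    A ring of sp2 atoms with unequal sides (e.g. pyridine's two shorter
    C-N bonds) cannot close with every interior angle at 120 deg.  The
    interior angles of the cyclic polygon realizing the target side lengths
    are exactly closable, so they replace the hybridization defaults;
    exocyclic angles at trigonal ring atoms take the symmetric remainder
    (360 - interior)/2.
    """
    g = nx.Graph()
    g.add_nodes_from(desc.atoms)
    g.add_edges_from((b.atom1, b.atom2) for b in desc.bonds)
    by_key = {a.key: a for a in desc.angles}
    for cyc in nx.cycle_basis(g):
        if len(cyc) < 4 or any(hybridization(desc, a) != 2 for a in cyc):
            continue
        sides = []
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            bond = desc.bond_between(a, b)
            if bond is None or bond.target is None:
                sides = None
                break
            sides.append(bond.target)
        if sides is None:
            continue
        central = _cyclic_polygon_angles(sides)
        if central is None:
            continue
        n = len(cyc)
        for k, vertex in enumerate(cyc):
            prev_atom = cyc[(k - 1) % n]
            next_atom = cyc[(k + 1) % n]
            interior = 180.0 - 0.5 * (central[(k - 1) % n] + central[k])
            interior = round(interior, 2)
            key = AngleRestraint(prev_atom, vertex, next_atom).key
            if key in by_key:
                by_key[key].target = interior
            if len(desc.neighbours(vertex)) == 3:
                exo = round((360.0 - interior) / 2.0, 2)
                for nbr in desc.neighbours(vertex):
                    if nbr in (prev_atom, next_atom):
                        continue
                    for ring_nbr in (prev_atom, next_atom):
                        key = AngleRestraint(ring_nbr, vertex, nbr).key
                        if key in by_key:
                            by_key[key].target = exo


def _cyclic_polygon_angles(sides):
    """Central angles (degrees) of the cyclic polygon with the given side
    lengths, or None when no circumscribed solution exists."""
    s = np.asarray(sides, float)
    lo = float(np.max(s)) / 2.0 + 1e-9

    def total(radius):
        return float(np.sum(2.0 * np.arcsin(np.clip(s / (2.0 * radius),
                                                    -1.0, 1.0))))

    if total(lo) < 2.0 * np.pi:
        return None
    hi = lo
    while total(hi) > 2.0 * np.pi:
        hi *= 2.0
        if hi > 1e6:
            return None
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if total(mid) > 2.0 * np.pi:
            lo = mid
        else:
            hi = mid
    radius = 0.5 * (lo + hi)
    return list(np.degrees(2.0 * np.arcsin(np.clip(s / (2.0 * radius),
                                                   -1.0, 1.0))))


def complete_description(desc: MonomerDescription, table: ParameterTable,
                         report: Optional[list] = None) -> MonomerDescription:
    """Extend a minimal description to a complete one.

    Declared chirality is preserved; newly detected stereocentres are given
    sign ``both`` since the graph alone does not orient them.  ``report``,
    when given, collects parameter-fallback notes.
    """
    out = desc.copy()
    if any(a.energy_type is None for a in out.atoms.values()):
        out = assign_energy_types(out)
    rings = ring_atoms(out)
    _ = rings
    defaults = table.defaults
    mark = len(table.fallback_log)

    for bond in out.bonds:
        t1 = out.atoms[bond.atom1].energy_type
        t2 = out.atoms[bond.atom2].energy_type
        e1 = out.atoms[bond.atom1].element
        e2 = out.atoms[bond.atom2].element
        bond.target, bond.sigma = table.bond(t1, t2, bond.order, e1, e2)

    out.angles = []
    for a, b, c in enumerate_angles(out):
        tdef = ideal_angle(out, b, defaults)
        t1 = out.atoms[a].energy_type
        t2 = out.atoms[b].energy_type
        t3 = out.atoms[c].energy_type
        target, sigma = table.angle(t1, t2, t3, tdef)
        out.angles.append(AngleRestraint(a, b, c, target, sigma))

    _apply_planar_ring_angles(out)

    out.torsions = []
    for i, (a, b, c, d) in enumerate(enumerate_torsions(out)):
        sp2 = hybridization(out, b) == 2 and hybridization(out, c) == 2
        period = 2 if sp2 else 3
        sigma = defaults.get("torsion_sp2_sigma", 5.0) if sp2 \
            else defaults.get("torsion_sp3_sigma", 15.0)
        out.torsions.append(TorsionRestraint(
            id=f"tor-{i + 1}", atom1=a, atom2=b, atom3=c, atom4=d,
            target=180.0, sigma=sigma, period=period))

    for centre, nbrs in detect_chiral_centres(out):
        out.chirals.append(ChiralCenter(
            id=f"chir-{len(out.chirals) + 1}", centre=centre,
            atom1=nbrs[0], atom2=nbrs[1], atom3=nbrs[2], sign="both"))

    out.planes = enumerate_planes(out, defaults)
    out.level = "complete"
    if report is not None:
        report.extend(table.fallback_log[mark:])
    return out


# ---------------------------------------------------------------------------
# coordinates -> description


@dataclass
class PdbAtom:
    name: str
    element: str
    xyz: tuple
    res_name: str = "UNL"


def read_pdb_atoms(text: str) -> list:
    """ATOM/HETATM records per PDB v3.3 fixed columns; element from columns
    77-78 with a name-derived fallback."""
    atoms = []
    for line in text.splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        name = line[12:16].strip()
        res = line[17:20].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            stripped = name.lstrip("0123456789")
            element = stripped[:2].strip().upper()
            if element not in _ATOMIC_NUMBER:
                element = stripped[:1].upper()
        atoms.append(PdbAtom(name=name, element=element.capitalize()
                             if len(element) == 2 else element,
                             xyz=(x, y, z), res_name=res))
    return atoms


def perceive_graph(atoms: list, table: Optional[ParameterTable] = None,
                   code: str = "UNL") -> MonomerDescription:
    """Minimal description from coordinates.

    Bonds connect atom pairs closer than the covalent-radii sum plus a
    tolerance; orders are then raised greedily, shortest bond first, while
    both partners have unused valence; chirality signs are read from the
    coordinates.
    """
    if not atoms:
        raise CoordinateError("no atoms to perceive")
    table = table or load_parameter_table()
    desc = MonomerDescription(code=code, level="minimal")
    coords = {}
    for a in atoms:
        desc.add_atom(AtomSpec(a.name, a.element, parent_ref=a.name))
        coords[a.name] = np.asarray(a.xyz, float)

    names = [a.name for a in atoms]
    for i, j in itertools.combinations(range(len(names)), 2):
        d = geometry.distance(coords[names[i]], coords[names[j]])
        if d < OVERLAP_LIMIT:
            raise CoordinateError(
                f"atoms {names[i]} and {names[j]} overlap ({d:.2f} A)")
        r = (table.radius(desc.atoms[names[i]].element)
             + table.radius(desc.atoms[names[j]].element))
        if d <= r + BOND_PERCEPTION_TOLERANCE:
            desc.add_bond(BondSpec(names[i], names[j], "single"))

    # greedy promotion to satisfy valence, shortest bonds first
    def free(name):
        atom = desc.atoms[name]
        return (effective_valence(atom.element, atom.charge)
                - math.floor(desc.bond_order_sum(name) + 1e-9))

    while True:
        candidates = [b for b in desc.bonds
                      if b.order in ("single", "double")
                      and free(b.atom1) >= 1 and free(b.atom2) >= 1
                      and not desc.atoms[b.atom1].is_hydrogen
                      and not desc.atoms[b.atom2].is_hydrogen]
        if not candidates:
            break
        best = min(candidates,
                   key=lambda b: geometry.distance(coords[b.atom1], coords[b.atom2]))
        best.order = "double" if best.order == "single" else "triple"

    for centre, nbrs in detect_chiral_centres(desc):
        vol = chiral_volume(coords[centre], *(coords[n] for n in nbrs))
        sign = chirality_sign(vol)
        desc.chirals.append(ChiralCenter(
            id=f"chir-{len(desc.chirals) + 1}", centre=centre,
            atom1=nbrs[0], atom2=nbrs[1], atom3=nbrs[2],
            sign=sign if sign != "degenerate" else "both"))
    return desc


def targets_from_coordinates(desc: MonomerDescription, coords: dict,
                             table: Optional[ParameterTable] = None
                             ) -> MonomerDescription:
    """Complete a description taking targets from observed geometry
    (the "as-is" mode).  The graph is left untouched; sigmas come from the
    table defaults."""
    table = table or load_parameter_table()
    missing = [n for n in desc.atoms if n not in coords]
    if missing:
        raise CoordinateError(f"no coordinate for atom {missing[0]}")
    out = desc.copy()
    if any(a.energy_type is None for a in out.atoms.values()):
        out = assign_energy_types(out)
    defaults = table.defaults
    pos = {n: np.asarray(coords[n], float) for n in out.atoms}

    bsig = defaults.get("bond_sigma", 0.02)
    asig = defaults.get("angle_sigma", 3.0)
    for bond in out.bonds:
        bond.target = round(geometry.distance(pos[bond.atom1], pos[bond.atom2]), 3)
        bond.sigma = bsig
    if not out.angles:
        out.angles = [AngleRestraint(a, b, c) for a, b, c in enumerate_angles(out)]
    for ang in out.angles:
        ang.target = round(geometry.angle_deg(
            pos[ang.atom1], pos[ang.atom2], pos[ang.atom3]), 2)
        ang.sigma = asig
    if not out.torsions:
        out.torsions = [
            TorsionRestraint(id=f"tor-{i + 1}", atom1=a, atom2=b, atom3=c,
                             atom4=d, period=1,
                             sigma=defaults.get("torsion_sp3_sigma", 15.0))
            for i, (a, b, c, d) in enumerate(enumerate_torsions(out))]
    for tor in out.torsions:
        tor.target = round(geometry.dihedral_deg(
            *(pos[n] for n in tor.atoms)), 2)
    if not out.planes:
        out.planes = enumerate_planes(out, defaults)
    for ch in out.chirals:
        vol = chiral_volume(pos[ch.centre],
                            *(pos[n] for n in ch.neighbours))
        sign = chirality_sign(vol)
        if sign != "degenerate":
            ch.sign = sign
    out.level = "complete"
    return out
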