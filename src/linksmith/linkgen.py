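"""Covalent-link generation: compose, regularize, split, apply.

The workflow mirrors an in-silico reaction: two (possibly pre-edited)
monomers are joined by a covalent bond into a composite compound
(:func:`compose`); composite atoms get unique names; hydrogens are
re-adjusted across the new bond; a complete description is generated from
scratch and idealized (:func:`regularize_session`); and finally the
composite is split into two modification entries plus one link entry
(:func:`split`): restraints spanning both monomers go to the link, while
each monomer's additions, deletions and super-sigma target shifts become
its modification.  :func:`apply_modification` and :func:`apply_link` are
the inverse direction and serve as the round-trip oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import cif_io
from .completion import ParameterTable, complete_description, load_parameter_table
from .entries import (
    LinkAngle,
    LinkBond,
    LinkChiral,
    LinkEntry,
    LinkPlaneAtom,
    LinkTorsion,
    ModAngleEdit,
    ModAtomEdit,
    ModBondEdit,
    ModChiralEdit,
    ModificationEntry,
    ModPlaneAtomEdit,
    ModTorsionEdit,
)
from .errors import (
    EditError,
    GroupMismatchError,
    LinksmithError,
    SerializationError,
    SessionError,
    ValenceError,
)
from .idealizer import IdealizerConfig, embed, regularize
from .molgraph import (
    AngleRestraint,
    AtomSpec,
    BondSpec,
    ChiralCenter,
    GraphEdit,
    MonomerDescription,
    PlaneGroup,
    TorsionRestraint,
    adjust_hydrogens,
    hydrogen_name,
)

#: a retained restraint is written as a change record once its target moves
#: by more than this multiple of the declared sigma
CHANGE_SIGMA_MULTIPLIER = 1.0


@dataclass
class CompositeSession:
    """Two monomer copies joined by one or more covalent link bonds."""

    mon_a: MonomerDescription
    mon_b: MonomerDescription
    original_a: MonomerDescription
    original_b: MonomerDescription
    link_bonds: list  # (atom_in_a, atom_in_b, order)
    unique_names: dict = field(default_factory=dict)  # (side, orig) -> unique
    restore_names: dict = field(default_factory=dict)  # unique -> (side, orig)
    composite: Optional[MonomerDescription] = None  # complete, unique names
    coords: Optional[dict] = None
    report: object = None
    auto_edits: dict = field(default_factory=lambda: {1: [], 2: []})
    regularized: bool = False
    locked: bool = True

    def side_monomer(self, side: int) -> MonomerDescription:
        return self.mon_a if side == 1 else self.mon_b

    def set_link_bond_order(self, index: int, order: str) -> None:
        """The one edit that stays allowed after composition."""
        a, b, _ = self.link_bonds[index]
        self.link_bonds[index] = (a, b, order)
        if self.composite is not None:
            self.composite = None
            self.coords = None
            self.regularized = False

    def require_regularized(self):
        if not self.regularized:
            raise SessionError("session must be regularized first")


def compose(mon_a: MonomerDescription, mon_b: MonomerDescription,
            bond: tuple,
            original_a: Optional[MonomerDescription] = None,
            original_b: Optional[MonomerDescription] = None
            ) -> CompositeSession:
    """Join two monomers (possibly two copies of the same compound) with a
    covalent bond ``(atom_in_a, atom_in_b, order)``.

    ``original_a``/``original_b`` are the pre-edit library descriptions the
    final modifications will be diffed against; they default to the passed
    monomers themselves.  Further editing of monomer internals is blocked;
    only the link-bond order stays adjustable.
    """
    atom_a, atom_b, order = bond
    if atom_a not in mon_a.atoms:
        raise EditError(f"link endpoint {atom_a!r} not in {mon_a.code}")
    if atom_b not in mon_b.atoms:
        raise EditError(f"link endpoint {atom_b!r} not in {mon_b.code}")
    a = mon_a.copy()
    b = mon_b.copy()
    for mon in (a, b):
        journalled_adds = set()
        for e in mon.journal:
            if e.kind == "add_atom":
                spec = e.payload.get("atom")
                journalled_adds.add(spec.name if isinstance(spec, AtomSpec)
                                    else spec["name"])
        for atom in mon.atoms.values():
            if atom.parent_ref is None and atom.name not in journalled_adds:
                atom.parent_ref = atom.name
    return CompositeSession(
        mon_a=a, mon_b=b,
        original_a=(original_a or mon_a).copy(),
        original_b=(original_b or mon_b).copy(),
        link_bonds=[(atom_a, atom_b, order)])


def side_naming(mon_a: MonomerDescription, mon_b: MonomerDescription):
    """Deterministic side-qualified unique naming for a composite.

    Names get a "1"/"2" side suffix; when that overflows four characters or
    still collides, an element-keyed counter steps in.  Returns
    (unique_names: (side, orig) -> unique, restore_names: inverse).
    """
    unique = {}
    restore = {}
    taken = set()
    for side, mon in ((1, mon_a), (2, mon_b)):
        for name, atom in mon.atoms.items():
            cand = f"{name}{side}"
            if len(cand) > 4 or cand in taken:
                i = 1
                el = atom.element.upper()[:1]
                while True:
                    cand = f"{el}{side}{i}"
                    if len(cand) <= 4 and cand not in taken:
                        break
                    i += 1
            taken.add(cand)
            unique[(side, name)] = cand
            restore[cand] = (side, name)
    return unique, restore


def make_unique_names(session: CompositeSession) -> CompositeSession:
    """Assign composite-wide unique atom names and the bijective restore
    map on the session."""
    session.unique_names, session.restore_names = side_naming(
        session.mon_a, session.mon_b)
    return session


def _build_composite_minimal(session: CompositeSession) -> MonomerDescription:
    if not session.unique_names:
        make_unique_names(session)
    u = session.unique_names
    comp = MonomerDescription(
        code=f"{session.mon_a.code}-{session.mon_b.code}", level="minimal")
    for side, mon in ((1, session.mon_a), (2, session.mon_b)):
        for name, atom in mon.atoms.items():
            comp.add_atom(AtomSpec(
                name=u[(side, name)], element=atom.element,
                charge=atom.charge, parent_ref=u[(side, name)]))
        for bond in mon.bonds:
            comp.add_bond(BondSpec(u[(side, bond.atom1)], u[(side, bond.atom2)],
                                   bond.order))
        for ch in mon.chirals:
            comp.chirals.append(ChiralCenter(
                id=f"{ch.id}-{side}", centre=u[(side, ch.centre)],
                atom1=u[(side, ch.atom1)], atom2=u[(side, ch.atom2)],
                atom3=u[(side, ch.atom3)], sign=ch.sign))
    for atom_a, atom_b, order in session.link_bonds:
        comp.add_bond(BondSpec(u[(1, atom_a)], u[(2, atom_b)], order))
    return comp


def regularize_session(session: CompositeSession,
                       table: Optional[ParameterTable] = None,
                       seed: int = 0,
                       config: Optional[IdealizerConfig] = None
                       ) -> CompositeSession:
    """Hydrogen adjustment, completion from scratch, and idealization of the
    composite compound.

    A valence violation at the link site (e.g. a double bond drawn to a
    carbon still carrying its aldehyde oxygen) is reported with advice to
    delete the clashing atom first.
    """
    table = table or load_parameter_table()
    comp = _build_composite_minimal(session)
    try:
        comp, edits = adjust_hydrogens(comp)
    except ValenceError as exc:
        where = session.restore_names.get(getattr(exc, "atom", None))
        at = (f"at atom {where[1]} of monomer {where[0]}" if where
              else "at the link site")
        raise ValenceError(
            f"{exc}; consider deleting an atom {at} before regularizing"
        ) from exc

    session.auto_edits = {1: [], 2: []}
    side_of = dict(session.restore_names)  # unique -> (side, orig)
    pending_bond = None
    for edit in edits:
        if edit.kind == "delete_atom":
            side, orig = side_of[edit.payload["name"]]
            session.auto_edits[side].append(
                GraphEdit("delete_atom", {"name": orig}))
        elif edit.kind == "add_atom":
            pending_bond = edit.payload["atom"].name
        elif edit.kind == "add_bond" and pending_bond is not None:
            hname = pending_bond
            pending_bond = None
            heavy_u = (edit.payload["atom1"]
                       if edit.payload["atom2"] == hname
                       else edit.payload["atom2"])
            side, heavy_orig = side_of[heavy_u]
            mon = session.side_monomer(side)
            taken = set(mon.atoms) | {o for (s, o) in side_of.values()
                                      if s == side}
            orig_h = hydrogen_name(heavy_orig,
                                   mon.atoms[heavy_orig].element, taken)
            side_of[hname] = (side, orig_h)
            session.unique_names[(side, orig_h)] = hname
            session.restore_names[hname] = (side, orig_h)
            session.auto_edits[side].append(
                GraphEdit("add_atom", {"atom": AtomSpec(orig_h, "H")}))
            session.auto_edits[side].append(
                GraphEdit("add_bond", {"atom1": heavy_orig, "atom2": orig_h,
                                       "order": "single"}))

    comp = complete_description(comp, table)
    start = embed(comp, seed=seed, config=config)
    coords, report = regularize(comp, start, config=config)
    session.composite = comp
    session.coords = coords
    session.report = report
    session.regularized = True
    return session


# ---------------------------------------------------------------------------
# splitting


def _sides_of(session: CompositeSession, names) -> set:
    return {session.restore_names[n][0] for n in names}


def _orig(session: CompositeSession, name: str) -> tuple:
    return session.restore_names[name]


def split(session: CompositeSession):
    """Split the regularized composite into (mod_a, mod_b, link).

    Cross-monomer restraints go to the link; per side, atoms/restraints are
    diffed against the original monomer via parent references, and a
    retained restraint becomes a change record only when its type changed
    or its target moved by more than the declared sigma.
    """
    session.require_regularized()
    comp = session.composite
    code_a = session.mon_a.code
    code_b = session.mon_b.code
    link_id = f"{code_a}-{code_b}"
    mod_ids = {1: f"{code_a}mod1",
               2: f"{code_b}mod2" if code_b == code_a else f"{code_b}mod1"}

    link = LinkEntry(id=link_id, name=link_id,
                     comp_id_1=code_a, mod_id_1=mod_ids[1],
                     comp_id_2=code_b, mod_id_2=mod_ids[2])
    per_side = {1: MonomerDescription(code=code_a, level="complete"),
                2: MonomerDescription(code=code_b, level="complete")}

    for uname, atom in comp.atoms.items():
        side, orig = _orig(session, uname)
        pre = session.side_monomer(side).atoms.get(orig)
        # chain the provenance back to the library monomer; hydrogens added
        # during regularization (no parent in the composite) stay parentless
        parent = pre.parent_ref if pre is not None else None
        if atom.parent_ref is None:
            parent = None
        per_side[side].add_atom(AtomSpec(
            name=orig, element=atom.element, energy_type=atom.energy_type,
            charge=atom.charge, parent_ref=parent))

    def refit(names):
        return tuple(_orig(session, n)[1] for n in names)

    def ref_sides(names):
        return tuple(_orig(session, n)[0] for n in names)

    for bond in comp.bonds:
        sides = _sides_of(session, (bond.atom1, bond.atom2))
        if len(sides) == 2:
            (s1, a1), (s2, a2) = _orig(session, bond.atom1), _orig(session, bond.atom2)
            if s1 == 2:
                (s1, a1), (s2, a2) = (s2, a2), (s1, a1)
            link.bonds.append(LinkBond(s1, a1, s2, a2, bond.order,
                                       bond.target, bond.sigma))
        else:
            side = sides.pop()
            per_side[side].bonds.append(BondSpec(
                *refit((bond.atom1, bond.atom2)), order=bond.order,
                target=bond.target, sigma=bond.sigma))

    for ang in comp.angles:
        names = (ang.atom1, ang.atom2, ang.atom3)
        sides = _sides_of(session, names)
        if len(sides) == 2:
            link.angles.append(LinkAngle(sides=ref_sides(names),
                                         atoms=refit(names),
                                         target=ang.target, sigma=ang.sigma))
        else:
            side = sides.pop()
            a, b, c = refit(names)
            per_side[side].angles.append(
                AngleRestraint(a, b, c, ang.target, ang.sigma))

    n_link_tor = 0
    for tor in comp.torsions:
        names = tor.atoms
        sides = _sides_of(session, names)
        if len(sides) == 2:
            n_link_tor += 1
            link.torsions.append(LinkTorsion(
                id=f"tor-{n_link_tor}", sides=ref_sides(names),
                atoms=refit(names), target=tor.target, sigma=tor.sigma,
                period=tor.period))
        else:
            side = sides.pop()
            a, b, c, d = refit(names)
            per_side[side].torsions.append(TorsionRestraint(
                id=tor.id, atom1=a, atom2=b, atom3=c, atom4=d,
                target=tor.target, sigma=tor.sigma, period=tor.period))

    n_link_chir = 0
    for ch in comp.chirals:
        names = (ch.centre,) + ch.neighbours
        sides = _sides_of(session, names)
        if len(sides) == 2:
            n_link_chir += 1
            cs, cn = _orig(session, ch.centre)
            link.chirals.append(LinkChiral(
                id=f"chir-{n_link_chir}", centre_side=cs, centre=cn,
                sides=ref_sides(ch.neighbours), atoms=refit(ch.neighbours),
                sign=ch.sign))
        else:
            side = sides.pop()
            n = refit(names)
            per_side[side].chirals.append(ChiralCenter(
                id=ch.id, centre=n[0], atom1=n[1], atom2=n[2], atom3=n[3],
                sign=ch.sign))

    n_link_plane = 0
    for plane in comp.planes:
        sides = _sides_of(session, plane.atoms)
        if len(sides) == 2:
            n_link_plane += 1
            for uname in plane.atoms:
                s, o = _orig(session, uname)
                link.planes.append(LinkPlaneAtom(
                    plane_id=f"plan-{n_link_plane}", side=s, atom=o,
                    sigma=plane.sigma_for(uname)))
        else:
            side = sides.pop()
            per_side[side].planes.append(PlaneGroup(
                id=plane.id, atoms=list(refit(plane.atoms)),
                sigma=plane.sigma))

    mod_a = _diff_monomer(mod_ids[1], session.original_a, per_side[1])
    mod_b = _diff_monomer(mod_ids[2], session.original_b, per_side[2])
    return mod_a, mod_b, link


def _diff_monomer(mod_id: str, orig: MonomerDescription,
                  new: MonomerDescription,
                  sigma_multiplier: float = CHANGE_SIGMA_MULTIPLIER
                  ) -> ModificationEntry:
    """Diff an edited, re-completed monomer against its original."""
    mod = ModificationEntry(id=mod_id, parent_code=orig.code,
                            name=f"modification of {orig.code}")
    surviving = {a.parent_ref for a in new.atoms.values()
                 if a.parent_ref is not None}
    deleted = [n for n in orig.atoms if n not in surviving]
    for name in deleted:
        mod.atom_edits.append(ModAtomEdit(function="delete", atom_id=name))
    for atom in new.atoms.values():
        if atom.parent_ref is None:
            mod.atom_edits.append(ModAtomEdit(
                function="add", new_atom_id=atom.name,
                new_element=atom.element, new_energy_type=atom.energy_type,
                new_charge=atom.charge))
        else:
            old = orig.atoms[atom.parent_ref]
            renamed = atom.parent_ref != atom.name
            if (renamed or old.energy_type != atom.energy_type
                    or old.charge != atom.charge
                    or old.element.upper() != atom.element.upper()):
                mod.atom_edits.append(ModAtomEdit(
                    function="change", atom_id=atom.parent_ref,
                    new_atom_id=atom.name if renamed else None,
                    new_element=atom.element if
                    old.element.upper() != atom.element.upper() else None,
                    new_energy_type=atom.energy_type
                    if old.energy_type != atom.energy_type else None,
                    new_charge=atom.charge if old.charge != atom.charge
                    else None))

    deleted_set = set(deleted)

    def touches_deleted(names):
        return any(n in deleted_set for n in names)

    parent_of = {a.name: a.parent_ref for a in new.atoms.values()}
    # atoms whose type/charge changed: restraints on them are regenerated
    # against the new types, so they must be re-recorded even when the
    # target happens to stay within sigma
    changed_atoms = set()
    for atom in new.atoms.values():
        if atom.parent_ref is None:
            continue
        old = orig.atoms[atom.parent_ref]
        if (old.energy_type != atom.energy_type or old.charge != atom.charge
                or old.element.upper() != atom.element.upper()):
            changed_atoms.add(atom.parent_ref)

    def retyped(parents):
        return any(p in changed_atoms for p in parents)

    # bonds -----------------------------------------------------------------
    old_bonds = {frozenset((b.atom1, b.atom2)): b for b in orig.bonds}
    seen = set()
    for b in new.bonds:
        p1, p2 = parent_of[b.atom1], parent_of[b.atom2]
        if p1 is None or p2 is None:
            mod.bond_edits.append(ModBondEdit(
                "add", b.atom1, b.atom2, b.order, b.target, b.sigma))
            continue
        key = frozenset((p1, p2))
        seen.add(key)
        ob = old_bonds.get(key)
        if ob is None:
            mod.bond_edits.append(ModBondEdit(
                "add", b.atom1, b.atom2, b.order, b.target, b.sigma))
        elif (ob.order != b.order or retyped((p1, p2))
              or _moved(ob.target, b.target, ob.sigma, sigma_multiplier)):
            mod.bond_edits.append(ModBondEdit(
                "change", b.atom1, b.atom2, b.order, b.target, b.sigma))
    for key, ob in old_bonds.items():
        if key not in seen and not touches_deleted(key):
            mod.bond_edits.append(ModBondEdit("delete", ob.atom1, ob.atom2))

    # angles ----------------------------------------------------------------
    old_angles = {a.key: a for a in orig.angles}
    seen = set()
    for a in new.angles:
        names = (a.atom1, a.atom2, a.atom3)
        if any(parent_of[n] is None for n in names):
            mod.angle_edits.append(ModAngleEdit(
                "add", *names, new_target=a.target, new_sigma=a.sigma))
            continue
        mapped = AngleRestraint(*(parent_of[n] for n in names))
        seen.add(mapped.key)
        oa = old_angles.get(mapped.key)
        if oa is None:
            mod.angle_edits.append(ModAngleEdit(
                "add", *names, new_target=a.target, new_sigma=a.sigma))
        elif (retyped(mapped.key)
              or _moved(oa.target, a.target, oa.sigma, sigma_multiplier)):
            mod.angle_edits.append(ModAngleEdit(
                "change", *names, new_target=a.target, new_sigma=a.sigma))
    for key, oa in old_angles.items():
        if key not in seen and not touches_deleted(key):
            mod.angle_edits.append(ModAngleEdit(
                "delete", oa.atom1, oa.atom2, oa.atom3))

    # torsions --------------------------------------------------------------
    old_tors = {t.key: t for t in orig.torsions}
    seen = set()
    for t in new.torsions:
        if any(parent_of[n] is None for n in t.atoms):
            mod.torsion_edits.append(ModTorsionEdit(
                "add", t.id, t.atoms, t.target, t.sigma, t.period))
            continue
        mapped = TorsionRestraint(t.id, *(parent_of[n] for n in t.atoms))
        seen.add(mapped.key)
        ot = old_tors.get(mapped.key)
        if ot is None:
            mod.torsion_edits.append(ModTorsionEdit(
                "add", t.id, t.atoms, t.target, t.sigma, t.period))
        elif (ot.period != t.period
              or retyped(tuple(parent_of[n] for n in t.atoms))
              or _moved_periodic(ot, t, sigma_multiplier)):
            mod.torsion_edits.append(ModTorsionEdit(
                "change", ot.id, t.atoms, t.target, t.sigma, t.period))
    for key, ot in old_tors.items():
        if key not in seen and not touches_deleted(key):
            mod.torsion_edits.append(ModTorsionEdit("delete", ot.id, ot.atoms))

    # chirals ---------------------------------------------------------------
    old_chir = {c.centre: c for c in orig.chirals}
    seen = set()
    for c in new.chirals:
        centre_parent = parent_of[c.centre]
        if centre_parent is None or any(parent_of[n] is None
                                        for n in c.neighbours):
            mod.chiral_edits.append(ModChiralEdit(
                "add", c.id, c.centre, c.neighbours, c.sign))
            continue
        seen.add(centre_parent)
        oc = old_chir.get(centre_parent)
        if oc is None:
            mod.chiral_edits.append(ModChiralEdit(
                "add", c.id, c.centre, c.neighbours, c.sign))
        elif (oc.sign != c.sign
              or tuple(map(parent_of.get, c.neighbours)) != oc.neighbours):
            mod.chiral_edits.append(ModChiralEdit(
                "change", oc.id, c.centre, c.neighbours, c.sign))
    for centre, oc in old_chir.items():
        if centre not in seen and not touches_deleted((centre,)
                                                      + oc.neighbours):
            mod.chiral_edits.append(ModChiralEdit(
                "delete", oc.id, oc.centre, oc.neighbours))

    # planes ----------------------------------------------------------------
    # a deleted atom silently leaves its plane group, so old planes are
    # matched on their surviving-atom sets
    old_planes = {}
    for p in orig.planes:
        reduced = frozenset(a for a in p.atoms if a not in deleted_set)
        old_planes[reduced] = p
    seen = set()
    for p in new.planes:
        parents = [parent_of[n] for n in p.atoms]
        key = frozenset(parents) if all(x is not None for x in parents) else None
        if key is not None and key in old_planes:
            seen.add(key)
            continue
        for atom in p.atoms:
            mod.plane_edits.append(ModPlaneAtomEdit(
                "add", p.id, atom, p.sigma_for(atom)))
    for key, op in old_planes.items():
        if key not in seen and len(key) >= 3:
            mod.plane_edits.append(ModPlaneAtomEdit("delete", op.id, None))
    return mod


def _moved(old, new, sigma, mult) -> bool:
    if old is None or new is None:
        return old != new
    s = sigma if sigma else 0.02
    return abs(new - old) > mult * s


def _moved_periodic(old_t, new_t, mult) -> bool:
    if old_t.target is None or new_t.target is None:
        return old_t.target != new_t.target
    from .geometry import wrap_periodic_dev
    dev = wrap_periodic_dev(new_t.target, old_t.target,
                            max(old_t.period, 1))
    s = old_t.sigma if old_t.sigma else 15.0
    return abs(dev) > mult * s


# ---------------------------------------------------------------------------
# applying


def apply_modification(mon: MonomerDescription,
                       mod: ModificationEntry) -> MonomerDescription:
    """Apply a modification's edits in order delete -> change -> add."""
    if mod.parent_code and mod.parent_code != mon.code \
            and mod.group_id not in ("", None) and mod.group_id != mon.group:
        raise GroupMismatchError(
            f"modification {mod.id} targets {mod.parent_code or mod.group_id}, "
            f"got {mon.code} ({mon.group})")
    out = mon.copy()

    # deletes
    for e in mod.atom_edits:
        if e.function == "delete":
            if e.atom_id not in out.atoms:
                raise EditError(
                    f"modification {mod.id} deletes absent atom {e.atom_id!r} "
                    f"from {mon.code}")
            del out.atoms[e.atom_id]
            out.bonds = [b for b in out.bonds
                         if e.atom_id not in (b.atom1, b.atom2)]
            out.drop_restraints_of(e.atom_id)
    for e in mod.bond_edits:
        if e.function == "delete":
            b = out.bond_between(e.atom1, e.atom2)
            if b is not None:
                out.bonds.remove(b)
    for e in mod.angle_edits:
        if e.function == "delete":
            key = AngleRestraint(e.atom1, e.atom2, e.atom3).key
            out.angles = [a for a in out.angles if a.key != key]
    for e in mod.torsion_edits:
        if e.function == "delete":
            key = TorsionRestraint("x", *e.atoms).key
            out.torsions = [t for t in out.torsions if t.key != key]
    for e in mod.chiral_edits:
        if e.function == "delete":
            out.chirals = [c for c in out.chirals if c.centre != e.centre]
    for e in mod.plane_edits:
        if e.function == "delete":
            out.planes = [p for p in out.planes if p.id != e.plane_id]

    # changes
    for e in mod.atom_edits:
        if e.function != "change":
            continue
        if e.atom_id not in out.atoms:
            raise EditError(f"modification {mod.id} changes absent atom "
                            f"{e.atom_id!r}")
        atom = out.atoms[e.atom_id]
        if e.new_element:
            atom.element = e.new_element
        if e.new_energy_type:
            atom.energy_type = e.new_energy_type
        if e.new_charge is not None:
            atom.charge = e.new_charge
        if e.new_atom_id and e.new_atom_id != e.atom_id:
            out.rename_atom(e.atom_id, e.new_atom_id)
    for e in mod.bond_edits:
        if e.function != "change":
            continue
        b = out.bond_between(e.atom1, e.atom2)
        if b is None:
            raise EditError(f"modification {mod.id} changes absent bond "
                            f"{e.atom1}-{e.atom2}")
        if e.new_order:
            b.order = e.new_order
        if e.new_target is not None:
            b.target = e.new_target
        if e.new_sigma is not None:
            b.sigma = e.new_sigma
    for e in mod.angle_edits:
        if e.function != "change":
            continue
        key = AngleRestraint(e.atom1, e.atom2, e.atom3).key
        for a in out.angles:
            if a.key == key:
                if e.new_target is not None:
                    a.target = e.new_target
                if e.new_sigma is not None:
                    a.sigma = e.new_sigma
                break
        else:
            raise EditError(f"modification {mod.id} changes absent angle "
                            f"{e.atom1}-{e.atom2}-{e.atom3}")
    for e in mod.torsion_edits:
        if e.function != "change":
            continue
        key = TorsionRestraint("x", *e.atoms).key
        for t in out.torsions:
            if t.key == key:
                if e.new_target is not None:
                    t.target = e.new_target
                if e.new_sigma is not None:
                    t.sigma = e.new_sigma
                if e.new_period is not None:
                    t.period = e.new_period
                break
    for e in mod.chiral_edits:
        if e.function != "change":
            continue
        for c in out.chirals:
            if c.centre == e.centre:
                if e.new_sign:
                    c.sign = e.new_sign
                if e.atoms and all(e.atoms):
                    c.atom1, c.atom2, c.atom3 = e.atoms
                break

    # adds
    for e in mod.atom_edits:
        if e.function == "add":
            out.add_atom(AtomSpec(
                name=e.new_atom_id, element=e.new_element or "C",
                energy_type=e.new_energy_type, charge=e.new_charge or 0,
                parent_ref=None))
    for e in mod.bond_edits:
        if e.function == "add":
            out.add_bond(BondSpec(e.atom1, e.atom2,
                                  e.new_order or "single",
                                  e.new_target, e.new_sigma))
    for e in mod.angle_edits:
        if e.function == "add":
            out.angles.append(AngleRestraint(
                e.atom1, e.atom2, e.atom3, e.new_target, e.new_sigma))
    for e in mod.torsion_edits:
        if e.function == "add":
            out.torsions.append(TorsionRestraint(
                e.id, *e.atoms, target=e.new_target, sigma=e.new_sigma,
                period=e.new_period or 1))
    for e in mod.chiral_edits:
        if e.function == "add":
            out.chirals.append(ChiralCenter(
                e.id, e.centre, *e.atoms, sign=e.new_sign or "both"))
    new_planes = {}
    for e in mod.plane_edits:
        if e.function == "add":
            new_planes.setdefault(e.plane_id, []).append(
                (e.atom_id, e.new_sigma or 0.02))
    for pid, members in new_planes.items():
        out.planes.append(PlaneGroup(
            id=pid, atoms=[m[0] for m in members], sigma=members[0][1],
            atom_sigmas={m[0]: m[1] for m in members
                         if m[1] != members[0][1]}))
    return out


def _check_side(link: LinkEntry, side: int, mon: MonomerDescription) -> None:
    comp = getattr(link, f"comp_id_{side}")
    group = getattr(link, f"group_comp_{side}")
    if comp:
        if comp != mon.code:
            raise GroupMismatchError(
                f"link {link.id} side {side} requires compound {comp}, "
                f"got {mon.code}")
    elif group:
        if group != mon.group:
            raise GroupMismatchError(
                f"link {link.id} side {side} requires group {group!r}, "
                f"got {mon.code} of group {mon.group!r}")


def apply_link(mon_a: MonomerDescription, mon_b: MonomerDescription,
               mod_a: Optional[ModificationEntry],
               mod_b: Optional[ModificationEntry],
               link: LinkEntry) -> MonomerDescription:
    """Modified A + modified B + the link's cross restraints, with atom
    collisions resolved by the same side-qualified naming as the session."""
    _check_side(link, 1, mon_a)
    _check_side(link, 2, mon_b)
    a = apply_modification(mon_a, mod_a) if mod_a else mon_a.copy()
    b = apply_modification(mon_b, mod_b) if mod_b else mon_b.copy()

    u, _restore = side_naming(a, b)
    comp = MonomerDescription(code=f"{mon_a.code}-{mon_b.code}",
                              level="complete")
    for side, mon in ((1, a), (2, b)):
        for name, atom in mon.atoms.items():
            comp.add_atom(AtomSpec(
                name=u[(side, name)], element=atom.element,
                energy_type=atom.energy_type, charge=atom.charge,
                parent_ref=u[(side, name)]))
        for bond in mon.bonds:
            comp.add_bond(BondSpec(u[(side, bond.atom1)],
                                   u[(side, bond.atom2)], bond.order,
                                   bond.target, bond.sigma))
        for ang in mon.angles:
            comp.angles.append(AngleRestraint(
                u[(side, ang.atom1)], u[(side, ang.atom2)],
                u[(side, ang.atom3)], ang.target, ang.sigma))
        for tor in mon.torsions:
            comp.torsions.append(TorsionRestraint(
                tor.id, *(u[(side, n)] for n in tor.atoms),
                target=tor.target, sigma=tor.sigma, period=tor.period))
        for ch in mon.chirals:
            comp.chirals.append(ChiralCenter(
                f"{ch.id}-{side}", u[(side, ch.centre)],
                *(u[(side, n)] for n in ch.neighbours), sign=ch.sign))
        for plane in mon.planes:
            comp.planes.append(PlaneGroup(
                id=f"{plane.id}-{side}",
                atoms=[u[(side, n)] for n in plane.atoms],
                sigma=plane.sigma,
                atom_sigmas={u[(side, n)]: s
                             for n, s in plane.atom_sigmas.items()}))

    def lookup(side, name):
        try:
            return u[(side, name)]
        except KeyError:
            raise EditError(
                f"link {link.id} references atom {name!r} absent from "
                f"side {side}")

    for lb in link.bonds:
        comp.add_bond(BondSpec(lookup(lb.side1, lb.atom1),
                               lookup(lb.side2, lb.atom2), lb.order,
                               lb.target, lb.sigma))
    for la in link.angles:
        names = [lookup(s, n) for s, n in zip(la.sides, la.atoms)]
        comp.angles.append(AngleRestraint(*names, la.target, la.sigma))
    for lt in link.torsions:
        names = [lookup(s, n) for s, n in zip(lt.sides, lt.atoms)]
        comp.torsions.append(TorsionRestraint(
            lt.id, *names, target=lt.target, sigma=lt.sigma,
            period=lt.period))
    for lc in link.chirals:
        comp.chirals.append(ChiralCenter(
            lc.id, lookup(lc.centre_side, lc.centre),
            *(lookup(s, n) for s, n in zip(lc.sides, lc.atoms)),
            sign=lc.sign))
    planes = {}
    for lp in link.planes:
        planes.setdefault(lp.plane_id, []).append(
            (lookup(lp.side, lp.atom), lp.sigma))
    for pid, members in planes.items():
        comp.planes.append(PlaneGroup(
            id=pid, atoms=[m[0] for m in members], sigma=members[0][1]))
    return comp


def composite_signature(desc: MonomerDescription, restore: dict) -> dict:
    """Canonical, naming-independent view of a composite description.

    ``restore`` maps the composite's atom names to (side, original-name)
    pairs; the signature is what the split/apply round trip must preserve:
    atom set, bond set with orders and targets, and all restraint targets.
    """
    def so(name):
        return restore[name]

    atoms = {so(a.name): (a.element.upper(), a.energy_type, a.charge)
             for a in desc.atoms.values()}
    bonds = {frozenset((so(b.atom1), so(b.atom2))):
             (b.order, None if b.target is None else round(b.target, 6))
             for b in desc.bonds}
    angles = {}
    for a in desc.angles:
        e1, e3 = sorted((so(a.atom1), so(a.atom3)))
        angles[(e1, so(a.atom2), e3)] = (
            None if a.target is None else round(a.target, 6),
            None if a.sigma is None else round(a.sigma, 6))
    torsions = set()
    for t in desc.torsions:
        names = tuple(so(n) for n in t.atoms)
        torsions.add((min(names, names[::-1]),
                      None if t.target is None else round(t.target, 6),
                      t.period))
    chirals = {so(c.centre): (tuple(so(n) for n in c.neighbours), c.sign)
               for c in desc.chirals}
    planes = {frozenset(so(n) for n in p.atoms) for p in desc.planes}
    return {"atoms": atoms, "bonds": bonds, "angles": angles,
            "torsions": torsions, "chirals": chirals, "planes": planes}


# ---------------------------------------------------------------------------
# saving


def save_additional_library(session: CompositeSession,
                            path=None,
                            mode: str = "new",
                            base_library: Optional[cif_io.RestraintLibrary] = None,
                            include_monomers: bool = False):
    """Write (or merge-append) the additional library for a session.

    Emits mod list + link list + the two modifications + the link; a
    monomer block is included only when its code does not resolve in the
    declared base library.  Returns (library, text); ``path``, when given,
    receives the text.  In append mode the new entries take precedence and
    shadowing is logged as a warning on the returned library.
    """
    mod_a, mod_b, link = split(session)
    lib = cif_io.RestraintLibrary()

    for side, orig in ((1, session.original_a), (2, session.original_b)):
        resolvable = (base_library is not None
                      and orig.code in base_library.monomers)
        if include_monomers or not resolvable:
            if orig.code not in lib.monomers:
                lib.monomers[orig.code] = orig
                lib.label("comp", orig.code, "additional")
                if resolvable or (base_library is not None
                                  and orig.code in base_library.monomers):
                    lib.warnings.append(
                        f"monomer {orig.code!r} will shadow the base-library "
                        "entry of the same name")
    for mod in (mod_a, mod_b):
        if mod.id in lib.modifications:
            raise SerializationError(f"duplicate modification id {mod.id!r}")
        lib.modifications[mod.id] = mod
        lib.label("mod", mod.id, "additional")
    lib.links[link.id] = link
    lib.label("link", link.id, "additional")

    if mode == "append" and path is not None and Path(path).exists():
        existing = cif_io.read_library(Path(path).read_text())
        merged = cif_io.merge_libraries(existing, lib)
        lib = merged
    elif mode == "append" and path is None:
        raise LinksmithError("append mode needs a path to append to")
    elif mode == "new" and path is not None and Path(path).exists():
        existing = cif_io.read_library(Path(path).read_text())
        clash = (set(existing.modifications) & set(lib.modifications)
                 | set(existing.links) & set(lib.links))
        if clash:
            raise SerializationError(
                f"entry id(s) {sorted(clash)} already present; use append")

    text = cif_io.write_library(lib, include_comp_list=False)
    if path is not None:
        Path(path).write_text(text)
    return lib, text
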