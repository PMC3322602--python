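"""Restraint-dictionary CIF dialect (CCP4 monomer-library category scheme).

A library document holds list blocks (``data_comp_list``, ``data_mod_list``,
``data_link_list``) naming the entries, followed by one data block per
entry: ``data_comp_<CODE>``, ``data_mod_<ID>``, ``data_link_<ID>``.
Reading goes through gemmi's CIF parser; writing is done here so that the
output is deterministic and byte-stable (fixed block order, 3 decimals for
distances, 2 for angles, uniform quoting).

Entries from a user's *additional* library shadow same-named entries of the
standard library when the two are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import gemmi

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
from .errors import ConsistencyError, LibraryParseError, SerializationError
from .molgraph import (
    AngleRestraint,
    AtomSpec,
    BondSpec,
    ChiralCenter,
    MonomerDescription,
    PlaneGroup,
    TorsionRestraint,
)

#: documented defaults applied when a dictionary omits an esd
DEFAULT_BOND_SIGMA = 0.02   # A
DEFAULT_ANGLE_SIGMA = 3.0   # degrees

_SIGN_TO_CIF = {"positive": "positiv", "negative": "negativ", "both": "both"}
_SIGN_FROM_CIF = {v: k for k, v in _SIGN_TO_CIF.items()}

_KNOWN_COMP_CATS = ("_chem_comp_atom.", "_chem_comp_bond.", "_chem_comp_angle.",
                    "_chem_comp_tor.", "_chem_comp_chir.",
                    "_chem_comp_plane_atom.")
_KNOWN_MOD_CATS = ("_chem_mod_atom.", "_chem_mod_bond.", "_chem_mod_angle.",
                   "_chem_mod_tor.", "_chem_mod_chir.",
                   "_chem_mod_plane_atom.")
_KNOWN_LINK_CATS = ("_chem_link_bond.", "_chem_link_angle.", "_chem_link_tor.",
                    "_chem_link_chir.", "_chem_link_plane.")


@dataclass
class RestraintLibrary:
    """Monomer, modification and link entries plus per-entry provenance
    (``standard`` or ``additional``)."""

    monomers: dict = field(default_factory=dict)
    modifications: dict = field(default_factory=dict)
    links: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)  # (kind, id) -> label
    warnings: list = field(default_factory=list)

    def label(self, kind: str, entry_id: str, source: str) -> None:
        self.provenance[(kind, entry_id)] = source

    def resolve_monomer(self, code: str) -> Optional[MonomerDescription]:
        return self.monomers.get(code)

    def unresolved_references(self, base: Optional["RestraintLibrary"] = None):
        """Modification parents and link mod-ids that resolve in neither
        this library nor ``base``."""
        missing = []

        def has_comp(code):
            return (code in self.monomers
                    or (base is not None and code in base.monomers))

        def has_mod(mid):
            return (mid in self.modifications
                    or (base is not None and mid in base.modifications))

        for mod in self.modifications.values():
            if mod.parent_code and not has_comp(mod.parent_code):
                missing.append(("mod", mod.id, mod.parent_code))
        for link in self.links.values():
            for mid in (link.mod_id_1, link.mod_id_2):
                if mid and not has_mod(mid):
                    missing.append(("link", link.id, mid))
            for code in (link.comp_id_1, link.comp_id_2):
                if code and not has_comp(code):
                    missing.append(("link", link.id, code))
        return missing


def merge_libraries(standard: RestraintLibrary,
                    additional: RestraintLibrary) -> RestraintLibrary:
    """Overlay ``additional`` on ``standard``; on id collision the
    additional entry wins and a shadowing warning is recorded."""
    out = RestraintLibrary()
    for code, m in standard.monomers.items():
        out.monomers[code] = m
        out.label("comp", code, standard.provenance.get(("comp", code), "standard"))
    for mid, m in standard.modifications.items():
        out.modifications[mid] = m
        out.label("mod", mid, standard.provenance.get(("mod", mid), "standard"))
    for lid, l in standard.links.items():
        out.links[lid] = l
        out.label("link", lid, standard.provenance.get(("link", lid), "standard"))
    for kind, entries in (("comp", additional.monomers),
                          ("mod", additional.modifications),
                          ("link", additional.links)):
        target = {"comp": out.monomers, "mod": out.modifications,
                  "link": out.links}[kind]
        for eid, entry in entries.items():
            if eid in target:
                out.warnings.append(
                    f"additional {kind} entry {eid!r} shadows the standard one")
            target[eid] = entry
            out.label(kind, eid, "additional")
    return out


# ---------------------------------------------------------------------------
# value helpers


def _none(v: Optional[str]) -> Optional[str]:
    # gemmi's as_string maps the CIF nulls '.'/'?' to ''
    return None if v in (None, "", ".", "?") else v


def _fnum(v: Optional[str]) -> Optional[float]:
    v = _none(v)
    return None if v is None else float(v)


def _inum(v: Optional[str]) -> Optional[int]:
    v = _none(v)
    return None if v is None else int(float(v))


def _fmt(v, nd: int) -> str:
    return "." if v is None else f"{v:.{nd}f}"


def _quote(v) -> str:
    if v is None or v == ".":
        return "."
    s = str(v)
    if s == "":
        return "''"
    needs = (any(ch.isspace() for ch in s) or s[0] in "_#$'\"[];"
             or s in ("?", "loop_") or s.lower().startswith("data_"))
    if not needs:
        return s
    if "'" not in s:
        return f"'{s}'"
    if '"' not in s:
        return f'"{s}"'
    raise SerializationError(f"cannot quote value {s!r}")


class _Writer:
    def __init__(self):
        self.parts = []

    def block(self, name: str):
        if self.parts:
            self.parts.append("")
        self.parts.append(f"data_{name}")

    def loop(self, category: str, tags: list, rows: list):
        if not rows:
            return
        self.parts.append("loop_")
        for tag in tags:
            self.parts.append(f"{category}{tag}")
        for row in rows:
            self.parts.append(" ".join(_quote(v) for v in row))

    def raw_loop(self, tags: list, rows: list):
        if not rows:
            return
        self.parts.append("loop_")
        self.parts.extend(tags)
        for row in rows:
            self.parts.append(" ".join(row))

    def text(self) -> str:
        return "\n".join(self.parts) + "\n"


# ---------------------------------------------------------------------------
# reading


def _table(block, prefix: str, tags: list):
    return block.find(prefix, tags)


def _cell(row, i) -> Optional[str]:
    if not row.has(i):
        return None
    return _none(gemmi.cif.as_string(row[i]))


def read_library(text: str, source: str = "additional") -> RestraintLibrary:
    """Parse a restraint-dictionary document.

    ``source`` labels the provenance of every entry read.  Unknown
    categories inside entry blocks are kept verbatim for round-tripping.
    """
    try:
        doc = gemmi.cif.read_string(text)
    except (ValueError, RuntimeError) as exc:
        raise LibraryParseError(str(exc)) from exc

    lib = RestraintLibrary()
    listed = {"comp": [], "mod": [], "link": []}
    comp_meta, mod_meta, link_meta = {}, {}, {}

    for block in doc:
        bname = block.name
        if bname in ("comp_list", "mod_list", "link_list"):
            kind = bname.split("_")[0]
            tag = {"comp": "_chem_comp.id", "mod": "_chem_mod.id",
                   "link": "_chem_link.id"}[kind]
            col = block.find_loop(tag)
            listed[kind].extend(_none(gemmi.cif.as_string(v)) for v in col)
            if kind == "comp":
                comp_meta = _read_comp_list(block)
            elif kind == "mod":
                mod_meta = _read_mod_list(block)
            else:
                link_meta = _read_link_list(block)
            continue
        if bname.startswith("comp_"):
            desc = _read_monomer(block, bname[len("comp_"):])
            lib.monomers[desc.code] = desc
            lib.label("comp", desc.code, source)
        elif bname.startswith("mod_"):
            mod = _read_modification(block, bname[len("mod_"):])
            lib.modifications[mod.id] = mod
            lib.label("mod", mod.id, source)
        elif bname.startswith("link_"):
            link = _read_link(block, bname[len("link_"):])
            lib.links[link.id] = link
            lib.label("link", link.id, source)
        else:
            lib.warnings.append(f"ignoring unrecognized data block {bname!r}")

    for kind, store in (("comp", lib.monomers), ("mod", lib.modifications),
                        ("link", lib.links)):
        for eid in listed[kind]:
            if eid is not None and eid not in store:
                raise ConsistencyError(
                    f"{kind} list names entry {eid!r} but no data block "
                    f"{kind}_{eid} is present")

    for code, (name, group, level) in comp_meta.items():
        if code in lib.monomers:
            mon = lib.monomers[code]
            mon.name = name or mon.name
            mon.group = group or mon.group
            if level is not None:
                mon.level = "minimal" if level == "M" else "complete"
    for mid, (name, comp_id, group_id) in mod_meta.items():
        if mid in lib.modifications:
            mod = lib.modifications[mid]
            mod.name = name or mod.name
            mod.parent_code = comp_id or ""
            mod.group_id = group_id or ""
    for lid, meta in link_meta.items():
        if lid in lib.links:
            link = lib.links[lid]
            (link.comp_id_1, link.mod_id_1, link.group_comp_1,
             link.comp_id_2, link.mod_id_2, link.group_comp_2,
             name) = meta
            link.name = name or link.name
    return lib


def _read_comp_list(block) -> dict:
    out = {}
    tab = _table(block, "_chem_comp.",
                 ["id", "?three_letter_code", "?name", "?group",
                  "?number_atoms_all", "?number_atoms_nh", "?desc_level"])
    for row in tab:
        cid = _cell(row, 0)
        out[cid] = (_cell(row, 2), _cell(row, 3), _cell(row, 6))
    return out


def _read_mod_list(block) -> dict:
    out = {}
    tab = _table(block, "_chem_mod.",
                 ["id", "?name", "?comp_id", "?group_id"])
    for row in tab:
        out[_cell(row, 0)] = (_cell(row, 1), _cell(row, 2), _cell(row, 3))
    return out


def _read_link_list(block) -> dict:
    out = {}
    tab = _table(block, "_chem_link.",
                 ["id", "?comp_id_1", "?mod_id_1", "?group_comp_1",
                  "?comp_id_2", "?mod_id_2", "?group_comp_2", "?name"])
    for row in tab:
        out[_cell(row, 0)] = tuple(_cell(row, i) or "" for i in range(1, 7)
                                   ) + (_cell(row, 7),)
    return out


def _collect_extras(block, known_prefixes) -> dict:
    extra = {}
    for item in block:
        loop = item.loop
        if loop is None:
            pair = item.pair
            if pair is not None and not any(pair[0].startswith(p)
                                            for p in known_prefixes):
                extra.setdefault("__pairs__", []).append(list(pair))
            continue
        tags = list(loop.tags)
        if tags and not any(tags[0].startswith(p) for p in known_prefixes):
            width = loop.width()
            vals = list(loop.values)
            rows = [vals[i:i + width] for i in range(0, len(vals), width)]
            extra[tags[0]] = {"tags": tags, "rows": rows}
    return extra


def _read_monomer(block, code: str) -> MonomerDescription:
    desc = MonomerDescription(code=code)
    for row in _table(block, "_chem_comp_atom.",
                      ["atom_id", "type_symbol", "?type_energy",
                       "?partial_charge"]):
        desc.add_atom(AtomSpec(
            name=_cell(row, 0), element=_cell(row, 1),
            energy_type=_cell(row, 2),
            charge=_inum(_cell(row, 3)) or 0,
            parent_ref=_cell(row, 0)))
    try:
        for row in _table(block, "_chem_comp_bond.",
                          ["atom_id_1", "atom_id_2", "?type", "?value_dist",
                           "?value_dist_esd"]):
            target = _fnum(_cell(row, 3))
            sigma = _fnum(_cell(row, 4))
            if target is not None and sigma is None:
                sigma = DEFAULT_BOND_SIGMA
            desc.add_bond(BondSpec(
                atom1=_cell(row, 0), atom2=_cell(row, 1),
                order=_cell(row, 2) or "single", target=target, sigma=sigma))
        for row in _table(block, "_chem_comp_angle.",
                          ["atom_id_1", "atom_id_2", "atom_id_3",
                           "?value_angle", "?value_angle_esd"]):
            sigma = _fnum(_cell(row, 4))
            target = _fnum(_cell(row, 3))
            if target is not None and sigma is None:
                sigma = DEFAULT_ANGLE_SIGMA
            desc.angles.append(AngleRestraint(
                _cell(row, 0), _cell(row, 1), _cell(row, 2), target, sigma))
        for row in _table(block, "_chem_comp_tor.",
                          ["id", "atom_id_1", "atom_id_2", "atom_id_3",
                           "atom_id_4", "?value_angle", "?value_angle_esd",
                           "?period"]):
            desc.torsions.append(TorsionRestraint(
                id=_cell(row, 0), atom1=_cell(row, 1), atom2=_cell(row, 2),
                atom3=_cell(row, 3), atom4=_cell(row, 4),
                target=_fnum(_cell(row, 5)), sigma=_fnum(_cell(row, 6)),
                period=_inum(_cell(row, 7)) or 1))
        for row in _table(block, "_chem_comp_chir.",
                          ["id", "atom_id_centre", "atom_id_1", "atom_id_2",
                           "atom_id_3", "volume_sign"]):
            desc.chirals.append(ChiralCenter(
                id=_cell(row, 0), centre=_cell(row, 1), atom1=_cell(row, 2),
                atom2=_cell(row, 3), atom3=_cell(row, 4),
                sign=_SIGN_FROM_CIF.get(_cell(row, 5), "both")))
        planes = {}
        for row in _table(block, "_chem_comp_plane_atom.",
                          ["plane_id", "atom_id", "?dist_esd"]):
            pid = _cell(row, 0)
            planes.setdefault(pid, []).append(
                (_cell(row, 1), _fnum(_cell(row, 2)) or 0.02))
        for pid, members in planes.items():
            desc.planes.append(PlaneGroup(
                id=pid, atoms=[m[0] for m in members],
                sigma=members[0][1],
                atom_sigmas={m[0]: m[1] for m in members
                             if m[1] != members[0][1]}))
    except (TypeError, ValueError) as exc:
        raise LibraryParseError(f"block comp_{code}: {exc}") from exc

    has_targets = any(b.target is not None for b in desc.bonds)
    desc.level = "complete" if (has_targets or desc.angles) else "minimal"
    desc.extra = _collect_extras(block, _KNOWN_COMP_CATS + ("_chem_comp.",))
    return desc


def _read_modification(block, mid: str) -> ModificationEntry:
    mod = ModificationEntry(id=mid)
    for row in _table(block, "_chem_mod_atom.",
                      ["function", "atom_id", "?new_atom_id",
                       "?new_type_symbol", "?new_type_energy", "?new_charge"]):
        mod.atom_edits.append(ModAtomEdit(
            function=_cell(row, 0), atom_id=_cell(row, 1),
            new_atom_id=_cell(row, 2), new_element=_cell(row, 3),
            new_energy_type=_cell(row, 4), new_charge=_inum(_cell(row, 5))))
    for row in _table(block, "_chem_mod_bond.",
                      ["function", "atom_id_1", "atom_id_2", "?new_type",
                       "?new_value_dist", "?new_value_dist_esd"]):
        mod.bond_edits.append(ModBondEdit(
            function=_cell(row, 0), atom1=_cell(row, 1), atom2=_cell(row, 2),
            new_order=_cell(row, 3), new_target=_fnum(_cell(row, 4)),
            new_sigma=_fnum(_cell(row, 5))))
    for row in _table(block, "_chem_mod_angle.",
                      ["function", "atom_id_1", "atom_id_2", "atom_id_3",
                       "?new_value_angle", "?new_value_angle_esd"]):
        mod.angle_edits.append(ModAngleEdit(
            function=_cell(row, 0), atom1=_cell(row, 1), atom2=_cell(row, 2),
            atom3=_cell(row, 3), new_target=_fnum(_cell(row, 4)),
            new_sigma=_fnum(_cell(row, 5))))
    for row in _table(block, "_chem_mod_tor.",
                      ["function", "id", "atom_id_1", "atom_id_2", "atom_id_3",
                       "atom_id_4", "?new_value_angle", "?new_value_angle_esd",
                       "?new_period"]):
        mod.torsion_edits.append(ModTorsionEdit(
            function=_cell(row, 0), id=_cell(row, 1),
            atoms=tuple(_cell(row, i) for i in range(2, 6)),
            new_target=_fnum(_cell(row, 6)), new_sigma=_fnum(_cell(row, 7)),
            new_period=_inum(_cell(row, 8))))
    for row in _table(block, "_chem_mod_chir.",
                      ["function", "id", "atom_id_centre", "atom_id_1",
                       "atom_id_2", "atom_id_3", "?new_volume_sign"]):
        mod.chiral_edits.append(ModChiralEdit(
            function=_cell(row, 0), id=_cell(row, 1), centre=_cell(row, 2),
            atoms=tuple(_cell(row, i) for i in range(3, 6)),
            new_sign=_SIGN_FROM_CIF.get(_cell(row, 6),
                                        _cell(row, 6))))
    for row in _table(block, "_chem_mod_plane_atom.",
                      ["function", "plane_id", "?atom_id", "?new_dist_esd"]):
        mod.plane_edits.append(ModPlaneAtomEdit(
            function=_cell(row, 0), plane_id=_cell(row, 1),
            atom_id=_cell(row, 2), new_sigma=_fnum(_cell(row, 3))))
    mod.extra = _collect_extras(block, _KNOWN_MOD_CATS + ("_chem_mod.",))
    return mod


def _read_link(block, lid: str) -> LinkEntry:
    link = LinkEntry(id=lid)
    for row in _table(block, "_chem_link_bond.",
                      ["atom_1_comp_id", "atom_id_1", "atom_2_comp_id",
                       "atom_id_2", "?type", "?value_dist", "?value_dist_esd"]):
        link.bonds.append(LinkBond(
            side1=_inum(_cell(row, 0)), atom1=_cell(row, 1),
            side2=_inum(_cell(row, 2)), atom2=_cell(row, 3),
            order=_cell(row, 4) or "single",
            target=_fnum(_cell(row, 5)), sigma=_fnum(_cell(row, 6))))
    for row in _table(block, "_chem_link_angle.",
                      ["atom_1_comp_id", "atom_id_1", "atom_2_comp_id",
                       "atom_id_2", "atom_3_comp_id", "atom_id_3",
                       "?value_angle", "?value_angle_esd"]):
        link.angles.append(LinkAngle(
            sides=tuple(_inum(_cell(row, i)) for i in (0, 2, 4)),
            atoms=tuple(_cell(row, i) for i in (1, 3, 5)),
            target=_fnum(_cell(row, 6)), sigma=_fnum(_cell(row, 7))))
    for row in _table(block, "_chem_link_tor.",
                      ["id", "atom_1_comp_id", "atom_id_1", "atom_2_comp_id",
                       "atom_id_2", "atom_3_comp_id", "atom_id_3",
                       "atom_4_comp_id", "atom_id_4", "?value_angle",
                       "?value_angle_esd", "?period"]):
        link.torsions.append(LinkTorsion(
            id=_cell(row, 0),
            sides=tuple(_inum(_cell(row, i)) for i in (1, 3, 5, 7)),
            atoms=tuple(_cell(row, i) for i in (2, 4, 6, 8)),
            target=_fnum(_cell(row, 9)), sigma=_fnum(_cell(row, 10)),
            period=_inum(_cell(row, 11)) or 1))
    for row in _table(block, "_chem_link_chir.",
                      ["id", "atom_centre_comp_id", "atom_id_centre",
                       "atom_1_comp_id", "atom_id_1", "atom_2_comp_id",
                       "atom_id_2", "atom_3_comp_id", "atom_id_3",
                       "?volume_sign"]):
        link.chirals.append(LinkChiral(
            id=_cell(row, 0), centre_side=_inum(_cell(row, 1)),
            centre=_cell(row, 2),
            sides=tuple(_inum(_cell(row, i)) for i in (3, 5, 7)),
            atoms=tuple(_cell(row, i) for i in (4, 6, 8)),
            sign=_SIGN_FROM_CIF.get(_cell(row, 9), "both")))
    for row in _table(block, "_chem_link_plane.",
                      ["plane_id", "atom_comp_id", "atom_id", "?dist_esd"]):
        link.planes.append(LinkPlaneAtom(
            plane_id=_cell(row, 0), side=_inum(_cell(row, 1)),
            atom=_cell(row, 2), sigma=_fnum(_cell(row, 3)) or 0.02))
    link.extra = _collect_extras(block, _KNOWN_LINK_CATS + ("_chem_link.",))
    return link


# ---------------------------------------------------------------------------
# writing


def write_library(lib: RestraintLibrary,
                  include_comp_list: bool = True) -> str:
    """Serialize a library deterministically.

    Block order: comp list, mod list, link list (each present only when the
    corresponding entries exist), then entries in insertion order.
    Additional-library files produced by save-as-link carry monomer blocks
    without a comp list (``include_comp_list=False``).
    """
    for code, mon in lib.monomers.items():
        _check_monomer(code, mon)
    for link in lib.links.values():
        if link.bonds and not link.crosses_sides():
            raise SerializationError(
                f"link entry {link.id!r} has no bond joining its two sides")

    w = _Writer()
    if lib.monomers and include_comp_list:
        w.block("comp_list")
        rows = []
        for code, mon in lib.monomers.items():
            n_all = len(mon.atoms)
            n_nh = len([a for a in mon.atoms.values() if not a.is_hydrogen])
            rows.append([code, code[:3], mon.name or code, mon.group,
                         str(n_all), str(n_nh),
                         "M" if mon.level == "minimal" else "."])
        w.loop("_chem_comp.", ["id", "three_letter_code", "name", "group",
                               "number_atoms_all", "number_atoms_nh",
                               "desc_level"], rows)
    if lib.modifications:
        w.block("mod_list")
        rows = []
        for mid, mod in lib.modifications.items():
            rows.append([mid, mod.name or mid, mod.parent_code or None,
                         mod.group_id or None])
        w.loop("_chem_mod.", ["id", "name", "comp_id", "group_id"], rows)
    if lib.links:
        w.block("link_list")
        rows = []
        for lid, link in lib.links.items():
            rows.append([lid, link.comp_id_1 or None, link.mod_id_1 or None,
                         link.group_comp_1 or None, link.comp_id_2 or None,
                         link.mod_id_2 or None, link.group_comp_2 or None,
                         link.name or lid])
        w.loop("_chem_link.", ["id", "comp_id_1", "mod_id_1", "group_comp_1",
                               "comp_id_2", "mod_id_2", "group_comp_2",
                               "name"], rows)

    for code, mon in lib.monomers.items():
        _write_monomer(w, code, mon)
    for mid, mod in lib.modifications.items():
        _write_modification(w, mid, mod)
    for lid, link in lib.links.items():
        _write_link(w, lid, link)
    return w.text()


def _check_monomer(code: str, mon: MonomerDescription) -> None:
    names = set(mon.atoms)
    refs = []
    for b in mon.bonds:
        refs.extend([b.atom1, b.atom2])
    for a in mon.angles:
        refs.extend([a.atom1, a.atom2, a.atom3])
    for t in mon.torsions:
        refs.extend(t.atoms)
    for c in mon.chirals:
        refs.extend([c.centre, *c.neighbours])
    for p in mon.planes:
        refs.extend(p.atoms)
    dangling = [r for r in refs if r not in names]
    if dangling:
        raise SerializationError(
            f"monomer {code!r} references unknown atom {dangling[0]!r}")


def _write_monomer(w: _Writer, code: str, mon: MonomerDescription) -> None:
    w.block(f"comp_{code}")
    w.loop("_chem_comp_atom.",
           ["comp_id", "atom_id", "type_symbol", "type_energy",
            "partial_charge"],
           [[code, a.name, a.element.upper(), a.energy_type or None,
             str(a.charge)] for a in mon.atoms.values()])
    w.loop("_chem_comp_bond.",
           ["comp_id", "atom_id_1", "atom_id_2", "type", "value_dist",
            "value_dist_esd"],
           [[code, b.atom1, b.atom2, b.order, _fmt(b.target, 3),
             _fmt(b.sigma, 3)] for b in mon.bonds])
    w.loop("_chem_comp_angle.",
           ["comp_id", "atom_id_1", "atom_id_2", "atom_id_3", "value_angle",
            "value_angle_esd"],
           [[code, a.atom1, a.atom2, a.atom3, _fmt(a.target, 2),
             _fmt(a.sigma, 2)] for a in mon.angles])
    w.loop("_chem_comp_tor.",
           ["comp_id", "id", "atom_id_1", "atom_id_2", "atom_id_3",
            "atom_id_4", "value_angle", "value_angle_esd", "period"],
           [[code, t.id, *t.atoms, _fmt(t.target, 2), _fmt(t.sigma, 2),
             str(t.period)] for t in mon.torsions])
    w.loop("_chem_comp_chir.",
           ["comp_id", "id", "atom_id_centre", "atom_id_1", "atom_id_2",
            "atom_id_3", "volume_sign"],
           [[code, c.id, c.centre, *c.neighbours, _SIGN_TO_CIF[c.sign]]
            for c in mon.chirals])
    rows = []
    for p in mon.planes:
        for atom in p.atoms:
            rows.append([code, p.id, atom, _fmt(p.sigma_for(atom), 3)])
    w.loop("_chem_comp_plane_atom.",
           ["comp_id", "plane_id", "atom_id", "dist_esd"], rows)
    _write_extras(w, mon.extra)


def _write_modification(w: _Writer, mid: str, mod: ModificationEntry) -> None:
    w.block(f"mod_{mid}")
    w.loop("_chem_mod_atom.",
           ["mod_id", "function", "atom_id", "new_atom_id", "new_type_symbol",
            "new_type_energy", "new_charge"],
           [[mid, e.function, e.atom_id, e.new_atom_id,
             e.new_element.upper() if e.new_element else None,
             e.new_energy_type,
             None if e.new_charge is None else str(e.new_charge)]
            for e in mod.atom_edits])
    w.loop("_chem_mod_bond.",
           ["mod_id", "function", "atom_id_1", "atom_id_2", "new_type",
            "new_value_dist", "new_value_dist_esd"],
           [[mid, e.function, e.atom1, e.atom2, e.new_order,
             _fmt(e.new_target, 3), _fmt(e.new_sigma, 3)]
            for e in mod.bond_edits])
    w.loop("_chem_mod_angle.",
           ["mod_id", "function", "atom_id_1", "atom_id_2", "atom_id_3",
            "new_value_angle", "new_value_angle_esd"],
           [[mid, e.function, e.atom1, e.atom2, e.atom3,
             _fmt(e.new_target, 2), _fmt(e.new_sigma, 2)]
            for e in mod.angle_edits])
    w.loop("_chem_mod_tor.",
           ["mod_id", "function", "id", "atom_id_1", "atom_id_2", "atom_id_3",
            "atom_id_4", "new_value_angle", "new_value_angle_esd",
            "new_period"],
           [[mid, e.function, e.id, *e.atoms, _fmt(e.new_target, 2),
             _fmt(e.new_sigma, 2),
             None if e.new_period is None else str(e.new_period)]
            for e in mod.torsion_edits])
    w.loop("_chem_mod_chir.",
           ["mod_id", "function", "id", "atom_id_centre", "atom_id_1",
            "atom_id_2", "atom_id_3", "new_volume_sign"],
           [[mid, e.function, e.id, e.centre, *e.atoms,
             _SIGN_TO_CIF.get(e.new_sign, e.new_sign)]
            for e in mod.chiral_edits])
    w.loop("_chem_mod_plane_atom.",
           ["mod_id", "function", "plane_id", "atom_id", "new_dist_esd"],
           [[mid, e.function, e.plane_id, e.atom_id, _fmt(e.new_sigma, 3)]
            for e in mod.plane_edits])
    _write_extras(w, mod.extra)


def _write_link(w: _Writer, lid: str, link: LinkEntry) -> None:
    w.block(f"link_{lid}")
    w.loop("_chem_link_bond.",
           ["link_id", "atom_1_comp_id", "atom_id_1", "atom_2_comp_id",
            "atom_id_2", "type", "value_dist", "value_dist_esd"],
           [[lid, str(b.side1), b.atom1, str(b.side2), b.atom2, b.order,
             _fmt(b.target, 3), _fmt(b.sigma, 3)] for b in link.bonds])
    w.loop("_chem_link_angle.",
           ["link_id", "atom_1_comp_id", "atom_id_1", "atom_2_comp_id",
            "atom_id_2", "atom_3_comp_id", "atom_id_3", "value_angle",
            "value_angle_esd"],
           [[lid, str(a.sides[0]), a.atoms[0], str(a.sides[1]), a.atoms[1],
             str(a.sides[2]), a.atoms[2], _fmt(a.target, 2),
             _fmt(a.sigma, 2)] for a in link.angles])
    w.loop("_chem_link_tor.",
           ["link_id", "id", "atom_1_comp_id", "atom_id_1", "atom_2_comp_id",
            "atom_id_2", "atom_3_comp_id", "atom_id_3", "atom_4_comp_id",
            "atom_id_4", "value_angle", "value_angle_esd", "period"],
           [[lid, t.id, str(t.sides[0]), t.atoms[0], str(t.sides[1]),
             t.atoms[1], str(t.sides[2]), t.atoms[2], str(t.sides[3]),
             t.atoms[3], _fmt(t.target, 2), _fmt(t.sigma, 2), str(t.period)]
            for t in link.torsions])
    w.loop("_chem_link_chir.",
           ["link_id", "id", "atom_centre_comp_id", "atom_id_centre",
            "atom_1_comp_id", "atom_id_1", "atom_2_comp_id", "atom_id_2",
            "atom_3_comp_id", "atom_id_3", "volume_sign"],
           [[lid, c.id, str(c.centre_side), c.centre, str(c.sides[0]),
             c.atoms[0], str(c.sides[1]), c.atoms[1], str(c.sides[2]),
             c.atoms[2], _SIGN_TO_CIF[c.sign]] for c in link.chirals])
    w.loop("_chem_link_plane.",
           ["link_id", "plane_id", "atom_comp_id", "atom_id", "dist_esd"],
           [[lid, p.plane_id, str(p.side), p.atom, _fmt(p.sigma, 3)]
            for p in link.planes])
    _write_extras(w, link.extra)


def _write_extras(w: _Writer, extra: dict) -> None:
    if not extra:
        return
    for key, payload in extra.items():
        if key == "__pairs__":
            for tag, value in payload:
                w.parts.append(f"{tag} {value}")
            continue
        w.raw_loop(payload["tags"], payload["rows"])
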