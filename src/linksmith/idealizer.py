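"""Restrained geometry idealization.

Generates Cartesian coordinates that satisfy a complete description:
:func:`embed` builds a rough starting conformation atom by atom from bond
and angle targets (random torsions from a seeded generator), and
:func:`regularize` minimizes a weighted least-squares objective

    sum_b (d-d0)^2/sigma^2 + sum_a (theta-theta0)^2/sigma^2
    + sum_t wrap(phi-phi0)^2/sigma^2 + sum_planes dist^2/sigma^2
    + chirality hinge + contact hinge

with a quasi-Newton minimizer (L-BFGS with analytic gradients).  The
chirality term is a one-sided quadratic on the signed volume, active only
when the volume is on the wrong side of a +-0.1 A^3 margin; plane terms use
the best-fit plane of the current coordinates, whose optimality makes the
fixed-plane gradient exact.  The contact hinge is a one-sided quadratic
keeping atom pairs beyond 1-3 topology outside an element-aware floor
(1.6 A H-H, 1.7 A X-H, 2.2 A heavy-heavy): dictionary terms alone leave
free torsions able to fold a molecule onto itself, which would corrupt
graph perception from the idealized coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from . import geometry
from .errors import CoordinateError, EmbedError
from .molgraph import MonomerDescription, chiral_volume

RAD2DEG = 180.0 / np.pi


@dataclass
class IdealizerConfig:
    """Tunable knobs of the minimizer; defaults suit dictionary-scale
    molecules (tens of atoms)."""

    max_iter: int = 4000
    chunk: int = 400           # iterations between convergence checks
    x_tol: float = 1e-4        # A, max coordinate move between checks
    g_tol: float = 1e-6        # max abs gradient component
    f_tol: float = 1e-5        # objective floor treated as fully satisfied
    chiral_margin: float = 0.1  # A^3
    chiral_sigma: float = 0.2   # A^3, weight of the chirality hinge
    min_spacing: float = 0.7    # A, embed clash floor (any pair)
    # contact floors (A) for pairs beyond 1-3 topology, by element class:
    # natural 1,3-diaxial H..H contacts sit near 1.85 A, polar X-H contacts
    # near 1.8 A, so the hinges engage only on genuinely folded geometry
    contact_floor_hh: float = 1.6
    contact_floor_xh: float = 1.7
    contact_floor_xx: float = 2.2
    nonbonded_sigma: float = 0.2  # A, weight of the contact hinge


@dataclass
class ResidualRow:
    kind: str
    atoms: tuple
    target: Optional[float]
    actual: float
    deviation: float
    deviation_over_sigma: float


@dataclass
class ResidualReport:
    rows: list = field(default_factory=list)
    maxima: dict = field(default_factory=dict)
    objective: float = 0.0
    iterations: int = 0
    converged: bool = False

    def max_deviation(self, kind: str) -> float:
        return self.maxima.get(kind, 0.0)


# ---------------------------------------------------------------------------
# compiled restraints


def _contact_floor(h1: bool, h2: bool, config) -> float:
    if h1 and h2:
        return config.contact_floor_hh
    if h1 or h2:
        return config.contact_floor_xh
    return config.contact_floor_xx


def _excluded_pairs(desc):
    """1-2 and 1-3 atom pairs, whose distances bonds and angles control."""
    nbrs = {n: set() for n in desc.atoms}
    for b in desc.bonds:
        nbrs[b.atom1].add(b.atom2)
        nbrs[b.atom2].add(b.atom1)
    excluded = {frozenset((b.atom1, b.atom2)) for b in desc.bonds}
    for centre, around in nbrs.items():
        for a in around:
            for b in around:
                if a != b:
                    excluded.add(frozenset((a, b)))
    return excluded


class _Compiled:
    def __init__(self, desc: MonomerDescription, config: IdealizerConfig):
        self.names = list(desc.atoms)
        self.index = {n: i for i, n in enumerate(self.names)}
        ix = self.index

        def sig(s, default):
            return s if s and s > 0 else default

        self.bonds = np.array(
            [[ix[b.atom1], ix[b.atom2]] for b in desc.bonds], dtype=int
        ).reshape(-1, 2)
        self.bond_t = np.array([b.target if b.target is not None else 1.5
                                for b in desc.bonds])
        self.bond_w = np.array([1.0 / sig(b.sigma, 0.02) ** 2 for b in desc.bonds])

        self.angles = np.array(
            [[ix[a.atom1], ix[a.atom2], ix[a.atom3]] for a in desc.angles],
            dtype=int).reshape(-1, 3)
        self.angle_t = np.array([a.target if a.target is not None else 109.47
                                 for a in desc.angles])
        self.angle_w = np.array([1.0 / sig(a.sigma, 3.0) ** 2 for a in desc.angles])

        self.torsions = np.array(
            [[ix[t.atom1], ix[t.atom2], ix[t.atom3], ix[t.atom4]]
             for t in desc.torsions], dtype=int).reshape(-1, 4)
        self.torsion_t = np.array([t.target if t.target is not None else 180.0
                                   for t in desc.torsions])
        self.torsion_p = np.array([max(t.period, 1) for t in desc.torsions],
                                  dtype=int).reshape(-1)
        self.torsion_w = np.array([1.0 / sig(t.sigma, 15.0) ** 2
                                   for t in desc.torsions])

        self.planes = [(np.array([ix[a] for a in p.atoms], dtype=int),
                        np.array([1.0 / sig(p.sigma_for(a), 0.02) ** 2
                                  for a in p.atoms]))
                       for p in desc.planes]

        self.chirals = [(ix[c.centre], ix[c.atom1], ix[c.atom2], ix[c.atom3],
                         c.sign) for c in desc.chirals if c.sign != "both"]
        self.chiral_margin = config.chiral_margin
        self.chiral_w = 1.0 / config.chiral_sigma ** 2

        # repulsive contact term: pairs beyond 1-3 are kept outside an
        # element-aware floor so free torsions cannot fold the molecule
        # onto itself
        excluded = _excluded_pairs(desc)
        names = self.names
        pairs = []
        floors = []
        is_h = {n: desc.atoms[n].is_hydrogen for n in names}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if frozenset((names[i], names[j])) in excluded:
                    continue
                pairs.append((i, j))
                floors.append(_contact_floor(is_h[names[i]],
                                             is_h[names[j]], config))
        self.nonbonded = np.array(pairs, dtype=int).reshape(-1, 2)
        self.nonbonded_floor = np.array(floors)
        self.nonbonded_w = 1.0 / config.nonbonded_sigma ** 2


def _objective(x: np.ndarray, comp: _Compiled):
    pos = x.reshape(-1, 3)
    f = 0.0
    g = np.zeros_like(pos)

    if len(comp.bonds):
        v = pos[comp.bonds[:, 0]] - pos[comp.bonds[:, 1]]
        d = np.linalg.norm(v, axis=1)
        dev = d - comp.bond_t
        f += float(np.sum(comp.bond_w * dev ** 2))
        coef = (2.0 * comp.bond_w * dev / np.maximum(d, 1e-12))[:, None] * v
        np.add.at(g, comp.bonds[:, 0], coef)
        np.add.at(g, comp.bonds[:, 1], -coef)

    if len(comp.angles):
        ia, ib, ic = comp.angles[:, 0], comp.angles[:, 1], comp.angles[:, 2]
        u = pos[ia] - pos[ib]
        v = pos[ic] - pos[ib]
        nu = np.maximum(np.linalg.norm(u, axis=1), 1e-12)
        nv = np.maximum(np.linalg.norm(v, axis=1), 1e-12)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cosang = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        dev = np.degrees(np.arccos(cosang)) - comp.angle_t
        f += float(np.sum(comp.angle_w * dev ** 2))
        sin = np.maximum(np.sqrt(1.0 - cosang ** 2), 1e-8)
        da = (cosang[:, None] * uh - vh) / (nu * sin)[:, None] * RAD2DEG
        dc = (cosang[:, None] * vh - uh) / (nv * sin)[:, None] * RAD2DEG
        coef = (2.0 * comp.angle_w * dev)[:, None]
        np.add.at(g, ia, coef * da)
        np.add.at(g, ic, coef * dc)
        np.add.at(g, ib, -coef * (da + dc))

    if len(comp.torsions):
        i1, i2 = comp.torsions[:, 0], comp.torsions[:, 1]
        i3, i4 = comp.torsions[:, 2], comp.torsions[:, 3]
        b1 = pos[i2] - pos[i1]
        b2 = pos[i3] - pos[i2]
        b3 = pos[i4] - pos[i3]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.maximum(np.linalg.norm(b2, axis=1), 1e-12)
        sq1 = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-12)
        sq2 = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-12)
        y = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / nb2[:, None])
        x = np.einsum("ij,ij->i", n1, n2)
        phi = np.degrees(np.arctan2(y, x))
        m = 360.0 / comp.torsion_p
        dev = (phi - comp.torsion_t + m / 2.0) % m - m / 2.0
        f += float(np.sum(comp.torsion_w * dev ** 2))
        d1 = -(nb2 / sq1)[:, None] * n1 * RAD2DEG
        d4 = (nb2 / sq2)[:, None] * n2 * RAD2DEG
        c12 = (np.einsum("ij,ij->i", b1, b2) / nb2 ** 2)[:, None]
        c32 = (np.einsum("ij,ij->i", b3, b2) / nb2 ** 2)[:, None]
        d2 = -(1.0 + c12) * d1 + c32 * d4
        d3 = c12 * d1 - (1.0 + c32) * d4
        coef = (2.0 * comp.torsion_w * dev)[:, None]
        np.add.at(g, i1, coef * d1)
        np.add.at(g, i2, coef * d2)
        np.add.at(g, i3, coef * d3)
        np.add.at(g, i4, coef * d4)

    for idx, w in comp.planes:
        pts = pos[idx]
        normal, centroid = geometry.best_fit_plane(pts, w)
        dist = (pts - centroid) @ normal
        f += float(np.sum(w * dist ** 2))
        # envelope theorem: plane parameters minimize the same sum, so the
        # fixed-plane gradient is exact
        contrib = (2.0 * w * dist)[:, None] * normal[None, :]
        np.add.at(g, idx, contrib)

    if len(comp.nonbonded):
        v = pos[comp.nonbonded[:, 0]] - pos[comp.nonbonded[:, 1]]
        d = np.linalg.norm(v, axis=1)
        close = d < comp.nonbonded_floor
        if close.any():
            gap = comp.nonbonded_floor[close] - d[close]
            f += float(np.sum(comp.nonbonded_w * gap ** 2))
            coef = (-2.0 * comp.nonbonded_w * gap
                    / np.maximum(d[close], 1e-9))[:, None] * v[close]
            np.add.at(g, comp.nonbonded[close, 0], coef)
            np.add.at(g, comp.nonbonded[close, 1], -coef)

    m = comp.chiral_margin
    for ic, i1, i2, i3, sign in comp.chirals:
        v1 = pos[i1] - pos[ic]
        v2 = pos[i2] - pos[ic]
        v3 = pos[i3] - pos[ic]
        vol = float(np.dot(v1, np.cross(v2, v3)))
        if sign == "positive":
            excess = vol - m
            active = excess < 0.0
        else:
            excess = vol + m
            active = excess > 0.0
        if active:
            f += comp.chiral_w * excess * excess
            coef = 2.0 * comp.chiral_w * excess
            d1 = np.cross(v2, v3)
            d2 = np.cross(v3, v1)
            d3 = np.cross(v1, v2)
            g[i1] += coef * d1
            g[i2] += coef * d2
            g[i3] += coef * d3
            g[ic] -= coef * (d1 + d2 + d3)

    return f, g.ravel()


# ---------------------------------------------------------------------------
# embedding


def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


def _ring_template(n: int, bond: float, planar: bool) -> np.ndarray:
    """Ideal ring coordinates: regular polygon, or a chair for saturated
    six-membered rings (tetrahedral vertex angles give +-60 deg ring
    torsions)."""
    angles = 2.0 * np.pi * np.arange(n) / n
    if planar or n != 6:
        r = bond / (2.0 * np.sin(np.pi / n))
        return np.stack([r * np.cos(angles), r * np.sin(angles),
                         np.zeros(n)], axis=1)
    target = np.radians(109.47)
    lo, hi = 0.0, bond / 2.0
    for _ in range(60):
        d = 0.5 * (lo + hi)
        r2 = bond * bond - 4.0 * d * d
        r = np.sqrt(max(r2, 1e-9))
        pts = np.stack([r * np.cos(angles), r * np.sin(angles),
                        d * (-1.0) ** np.arange(n)], axis=1)
        u = pts[0] - pts[1]
        v = pts[2] - pts[1]
        ang = np.arccos(np.clip(_unit(u) @ _unit(v), -1, 1))
        if ang > target:
            lo = d
        else:
            hi = d
    return pts


def _align_frames(u_t, w_t, u_l, rng, w_l_pref=None) -> np.ndarray:
    """Rotation taking template direction ``u_t`` to lab ``u_l``.

    The residual spin about the aligned axis is random (seeded) unless
    ``w_l_pref`` supplies a preferred in-plane direction for ``w_t``."""
    u_t = _unit(u_t)
    w_t = _unit(w_t - (w_t @ u_t) * u_t)
    frame_t = np.stack([u_t, w_t, np.cross(u_t, w_t)], axis=1)
    u_l = _unit(u_l)
    if w_l_pref is not None and np.linalg.norm(
            w_l_pref - (w_l_pref @ u_l) * u_l) > 1e-6:
        w_l = _unit(w_l_pref - (w_l_pref @ u_l) * u_l)
    else:
        arb = (np.array([1.0, 0.0, 0.0]) if abs(u_l[0]) < 0.9
               else np.array([0.0, 1.0, 0.0]))
        w0 = _unit(arb - (arb @ u_l) * u_l)
        spin = rng.uniform(0.0, 2.0 * np.pi)
        w_l = np.cos(spin) * w0 + np.sin(spin) * np.cross(u_l, w0)
    frame_l = np.stack([u_l, w_l, np.cross(u_l, w_l)], axis=1)
    return frame_l @ frame_t.T


def embed(desc: MonomerDescription, seed: int,
          config: Optional[IdealizerConfig] = None) -> dict:
    """Deterministic breadth-first placement from bond/angle targets.

    Torsions are drawn from a generator seeded with ``seed``; after
    placement, chiral centres with a declared sign that came out mirrored
    are fixed by reflecting the smallest pendant branch.
    """
    config = config or IdealizerConfig()
    if not desc.atoms:
        raise EmbedError("no atoms to embed")
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(desc.atoms)
    g.add_edges_from((b.atom1, b.atom2) for b in desc.bonds)
    if len(desc.atoms) > 1 and not nx.is_connected(g):
        raise EmbedError(f"graph of {desc.code} is disconnected")

    rng = np.random.default_rng(seed)
    excluded = _excluded_pairs(desc)
    unsaturated = set()
    for b in desc.bonds:
        if b.order != "single":
            unsaturated.update((b.atom1, b.atom2))
    bond_t = {}
    for b in desc.bonds:
        bond_t[frozenset((b.atom1, b.atom2))] = b.target if b.target else 1.5
    angle_t = {}
    for a in desc.angles:
        t = a.target if a.target else 109.47
        angle_t[(a.atom1, a.atom2, a.atom3)] = t
        angle_t[(a.atom3, a.atom2, a.atom1)] = t

    start = next(iter(desc.atoms))
    order = list(nx.bfs_tree(g, start))
    parent = {c: p for p, c in nx.bfs_edges(g, start)}
    pos = {start: np.zeros(3)}

    rings = [tuple(c) for c in nx.cycle_basis(g)]
    ring_of = {}
    for cyc in rings:
        for a in cyc:
            ring_of.setdefault(a, cyc)

    def ring_is_planar(cyc):
        multi = set()
        for b in desc.bonds:
            if b.order != "single":
                multi.update((b.atom1, b.atom2))
        return any(a in multi for a in cyc)

    def place_ring_substituent(name, p, cyc, d):
        """Exocyclic atom off a placed ring: equal angles to both ring
        neighbours; the two mirror solutions serve the (up to) two
        substituents of an sp3 ring atom."""
        i = cyc.index(p)
        r1, r2 = cyc[(i - 1) % len(cyc)], cyc[(i + 1) % len(cyc)]
        if r1 not in pos or r2 not in pos:
            return False
        u1 = _unit(pos[r1] - pos[p])
        u2 = _unit(pos[r2] - pos[p])
        cosg = float(u1 @ u2)
        theta = np.radians(angle_t.get((r1, p, name), 109.47))
        denom = 1.0 + cosg
        if abs(denom) < 1e-9:
            return False
        a = np.cos(theta) / denom
        s = u1 + u2
        m = np.cross(u1, u2)
        c2 = 1.0 - a * a * (2.0 + 2.0 * cosg)
        c = np.sqrt(max(c2, 0.0)) / max(np.linalg.norm(m), 1e-9)
        n_exo_placed = len([n for n in g[p] if n in pos and n not in cyc])
        v = a * s + (c if n_exo_placed % 2 == 0 else -c) * m
        pos[name] = pos[p] + d * _unit(v)
        return True

    def place(name):
        p = parent[name]
        d = bond_t[frozenset((name, p))]
        cyc_p = ring_of.get(p)
        if (cyc_p is not None and name not in cyc_p
                and all(a in pos for a in cyc_p)
                and place_ring_substituent(name, p, cyc_p, d)):
            return
        placed_nbrs = [n for n in g[p] if n in pos and n != name]
        if len(placed_nbrs) >= 2 and p in unsaturated and len(g[p]) == 3:
            # trigonal parent with two substituents down: the third slot is
            # the in-plane bisector, not a free cone position (hypervalent
            # atoms such as phosphate P stay on the cone path)
            u1 = _unit(pos[placed_nbrs[0]] - pos[p])
            u2 = _unit(pos[placed_nbrs[1]] - pos[p])
            v = -(u1 + u2)
            if np.linalg.norm(v) > 1e-6:
                pos[name] = pos[p] + d * _unit(v)
                return
        if not placed_nbrs:  # second atom overall
            pos[name] = pos[p] + np.array([d, 0.0, 0.0])
            return
        ref = parent.get(p) if parent.get(p) in pos else placed_nbrs[0]
        theta = np.radians(angle_t.get((ref, p, name), 109.47))
        # local frame along ref->p
        u = pos[p] - pos[ref]
        u = u / max(np.linalg.norm(u), 1e-9)
        arb = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        # third reference for the dihedral, if one exists
        ref2 = next((n for n in list(g[ref]) + list(g[p])
                     if n in pos and n not in (ref, p, name)), None)
        if ref2 is not None:
            w0 = pos[ref2] - pos[ref]
            perp = w0 - (w0 @ u) * u
            if np.linalg.norm(perp) > 1e-6:
                arb = perp
        v = arb - (arb @ u) * u
        v = v / max(np.linalg.norm(v), 1e-9)
        w = np.cross(u, v)

        # try a batch of torsion candidates and keep the most open one
        # (largest clearance over the topology-aware contact floors);
        # along a conjugated bond only the two in-plane slots are sensible
        if (p in unsaturated and ref in unsaturated
                and len(g[p]) <= 3 and len(g[ref]) <= 3):
            candidates = [0.0, np.pi]
        else:
            candidates = [rng.uniform(-np.pi, np.pi) for _ in range(24)]
        best_xyz, best_score = None, (-np.inf, -np.inf)
        centroid = np.mean(list(pos.values()), axis=0)
        for phi in candidates:
            xyz = pos[p] + d * (
                -np.cos(theta) * u
                + np.sin(theta) * (np.cos(phi) * v + np.sin(phi) * w))
            clearance = np.inf
            for n2, q in pos.items():
                if n2 == p:
                    continue
                sep = float(np.linalg.norm(xyz - q))
                floor = (config.min_spacing
                         if frozenset((name, n2)) in excluded
                         else _contact_floor(desc.atoms[name].is_hydrogen,
                                             desc.atoms[n2].is_hydrogen,
                                             config))
                clearance = min(clearance, sep - floor)
            # first satisfy the contact floors, then grow outward so that
            # chains extend instead of curling back
            score = (min(clearance, 0.0),
                     float(np.linalg.norm(xyz - centroid)))
            if score > best_score:
                best_xyz, best_score = xyz, score
        pos[name] = best_xyz

    def place_ring(cyc):
        """Drop a rigid ring template (planar polygon, or ideal chair for
        saturated six-rings) anchored at whatever is already placed."""
        b_mean = float(np.mean([bond_t[frozenset((a, b))]
                                for a, b in zip(cyc, cyc[1:] + cyc[:1])]))
        template = _ring_template(len(cyc), b_mean,
                                  planar=ring_is_planar(cyc))
        placed_in_ring = [a for a in cyc if a in pos]
        exo_atom = None
        if placed_in_ring:
            anchor = placed_in_ring[0]
            exo_nbrs = [n for n in g[anchor] if n in pos and n not in cyc]
            if exo_nbrs:
                exo_atom = exo_nbrs[0]
                exo_dir = pos[exo_atom] - pos[anchor]
            else:
                exo_dir = None
        else:
            # enter the ring through its first BFS atom placed normally
            entry = next(a for a in order if a in cyc)
            place(entry)
            anchor = entry
            exo_atom = parent[entry]
            exo_dir = pos[exo_atom] - pos[entry]
        i = cyc.index(anchor)
        t_prev = template[(i - 1) % len(cyc)] - template[i]
        t_next = template[(i + 1) % len(cyc)] - template[i]
        t_exo = -_unit(_unit(t_prev) + _unit(t_next))
        if exo_dir is None or np.linalg.norm(exo_dir) < 1e-9:
            exo_dir = rng.normal(size=3)
        # a planar ring hanging off an sp2 atom should start coplanar with
        # that atom's existing substituents, not at a random spin
        w_pref = None
        if (ring_is_planar(cyc) and exo_atom is not None
                and exo_atom in unsaturated):
            others = [n for n in g[exo_atom] if n in pos and n != anchor]
            if others:
                w_pref = pos[others[0]] - pos[exo_atom]
        rot = _align_frames(t_exo, _unit(t_next - t_prev),
                            _unit(exo_dir), rng, w_l_pref=w_pref)
        for k, a in enumerate(cyc):
            if a not in pos:
                pos[a] = pos[anchor] + rot @ (template[k] - template[i])

    for name in order[1:]:
        if name in pos:
            continue
        cyc = ring_of.get(name)
        if cyc is not None and not all(a in pos for a in cyc):
            place_ring(cyc)
        if name not in pos:
            place(name)

    _fix_embedded_chirality(desc, g, pos)
    _prerelax(desc, pos, config)
    _fix_embedded_chirality(desc, g, pos)
    return {n: np.asarray(p, float) for n, p in pos.items()}




def _prerelax(desc, pos, config):
    """Smoothing of the raw placement so that ring-closure bonds start
    near target (planes and chirality stay out; the contact hinge of the
    main objective keeps the start open).

    Tree placement satisfies bonds and angles along the spanning tree but
    not across ring closures; minimizing just the low-mode terms first
    avoids the torsion/plane local minima a cold start can fall into.
    """
    import networkx as nx
    comp = _Compiled(desc, config)
    comp.planes = []
    comp.chirals = []
    # keep only ring-bond torsions: they hold the ring template's pucker
    # while leaving substituent rotations free
    gg = nx.Graph()
    gg.add_edges_from((b.atom1, b.atom2) for b in desc.bonds)
    ring_edges = set()
    for cyc in nx.cycle_basis(gg):
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            ring_edges.add(frozenset((a, b)))
    if len(comp.torsions):
        keep = np.array([
            frozenset((comp.names[t[1]], comp.names[t[2]])) in ring_edges
            for t in comp.torsions], dtype=bool)
        comp.torsions = comp.torsions[keep]
        comp.torsion_t = comp.torsion_t[keep]
        comp.torsion_p = comp.torsion_p[keep]
        comp.torsion_w = comp.torsion_w[keep]
    names = comp.names
    x0 = np.array([pos[nm] for nm in names]).ravel()
    res = minimize(_objective, x0, args=(comp,), jac=True, method="L-BFGS-B",
                   options={"maxiter": 300, "ftol": 1e-12})
    for i, nm in enumerate(names):
        pos[nm] = res.x.reshape(-1, 3)[i]


def _fix_embedded_chirality(desc, g, pos):
    """Reflect pendant branches so declared chiral signs hold at the start."""
    import networkx as nx
    for ch in desc.chirals:
        if ch.sign not in ("positive", "negative"):
            continue
        vol = chiral_volume(pos[ch.centre], pos[ch.atom1], pos[ch.atom2],
                            pos[ch.atom3])
        if (vol > 0) == (ch.sign == "positive") and abs(vol) > 1e-6:
            continue
        h = g.copy()
        h.remove_node(ch.centre)
        comp_of = {}
        for comp in nx.connected_components(h):
            for n in comp:
                comp_of[n] = frozenset(comp)
        listed = list(ch.neighbours)
        comps = [comp_of[n] for n in listed]
        # keep the pair sharing a component (ring), else the two largest
        keep = None
        for i in range(3):
            for j in range(i + 1, 3):
                if comps[i] is comps[j] or comps[i] == comps[j]:
                    keep = {comps[i]}
        if keep is None:
            sizes = sorted(range(3), key=lambda i: -len(comps[i]))
            keep = {comps[sizes[0]], comps[sizes[1]]}
        if all(c in keep for c in comps):
            continue  # fully ring-locked, the hinge term will handle it
        kept_nbrs = [n for n in listed if comp_of[n] in keep][:2]
        if len(kept_nbrs) < 2:
            continue
        c0 = pos[ch.centre]
        n_vec = np.cross(pos[kept_nbrs[0]] - c0, pos[kept_nbrs[1]] - c0)
        nn = np.linalg.norm(n_vec)
        if nn < 1e-9:
            continue
        n_vec = n_vec / nn
        for n in g[ch.centre]:
            comp = comp_of[n]
            if comp in keep:
                continue
            for atom in comp:
                rel = pos[atom] - c0
                pos[atom] = pos[atom] - 2.0 * (rel @ n_vec) * n_vec


# ---------------------------------------------------------------------------
# minimization and reporting


def _coords_vector(desc, coords):
    missing = [n for n in desc.atoms if n not in coords]
    if missing:
        raise CoordinateError(f"no coordinate for atom {missing[0]}")
    return np.array([coords[n] for n in desc.atoms], float).ravel()


def regularize(desc: MonomerDescription, coords: dict,
               config: Optional[IdealizerConfig] = None):
    """Minimize the restraint objective from ``coords``.

    Runs L-BFGS in chunks; converged once the largest coordinate move
    between chunks drops below ``x_tol`` or the gradient below ``g_tol``.
    Non-convergence is reported, not raised.  Returns (coords, report).
    """
    config = config or IdealizerConfig()
    comp = _Compiled(desc, config)
    x = _coords_vector(desc, coords)
    f_start = _objective(x, comp)[0]

    total_iter = 0
    converged = False
    while total_iter < config.max_iter:
        res = minimize(_objective, x, args=(comp,), jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": config.chunk, "ftol": 1e-14,
                                "gtol": 1e-12, "maxls": 60})
        step = float(np.max(np.abs(res.x - x))) if res.nit else 0.0
        x = res.x
        total_iter += res.nit
        gmax = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        if (res.fun < config.f_tol or gmax < config.g_tol
                or step < config.x_tol or res.nit < config.chunk):
            # an interior stop of the line search means no further progress
            # at working precision: a stationary point for our purposes
            converged = True
            break

    out = {n: x.reshape(-1, 3)[i].copy() for i, n in enumerate(desc.atoms)}

    # a declared chirality can survive minimization with the wrong sign:
    # inverting a tetrahedral centre crosses an angle-strain barrier the
    # local minimizer will not climb.  Reflect the offending branch and
    # re-minimize (at most twice).
    for _ in range(2):
        wrong = [c for c in desc.chirals if c.sign in ("positive", "negative")
                 and (chiral_volume(out[c.centre], out[c.atom1], out[c.atom2],
                                    out[c.atom3]) > 0) != (c.sign == "positive")]
        if not wrong:
            break
        import networkx as nx
        gg = nx.Graph()
        gg.add_nodes_from(desc.atoms)
        gg.add_edges_from((b.atom1, b.atom2) for b in desc.bonds)
        _fix_embedded_chirality(desc, gg, out)
        res = minimize(_objective, np.array(list(out.values())).ravel(),
                       args=(comp,), jac=True, method="L-BFGS-B",
                       options={"maxiter": config.max_iter, "ftol": 1e-14,
                                "gtol": 1e-12, "maxls": 60})
        total_iter += res.nit
        out = {n: res.x.reshape(-1, 3)[i].copy()
               for i, n in enumerate(desc.atoms)}
        x = res.x

    f_end, _ = _objective(x, comp)
    if f_end > f_start:  # never accept an uphill result
        out = dict(coords)
        out = {n: np.asarray(out[n], float).copy() for n in desc.atoms}
    report = residuals(desc, out, config)
    report.iterations = total_iter
    report.converged = converged
    return out, report


def residuals(desc: MonomerDescription, coords: dict,
              config: Optional[IdealizerConfig] = None) -> ResidualReport:
    """Pure evaluation of every restraint against the coordinates."""
    config = config or IdealizerConfig()
    comp = _Compiled(desc, config)
    x = _coords_vector(desc, coords)
    pos = {n: np.asarray(coords[n], float) for n in desc.atoms}
    rows = []

    for b in desc.bonds:
        d = geometry.distance(pos[b.atom1], pos[b.atom2])
        t = b.target if b.target is not None else d
        s = b.sigma if b.sigma else 0.02
        rows.append(ResidualRow("bond", (b.atom1, b.atom2), t, d, d - t,
                                (d - t) / s))
    for a in desc.angles:
        th = geometry.angle_deg(pos[a.atom1], pos[a.atom2], pos[a.atom3])
        t = a.target if a.target is not None else th
        s = a.sigma if a.sigma else 3.0
        rows.append(ResidualRow("angle", (a.atom1, a.atom2, a.atom3), t, th,
                                th - t, (th - t) / s))
    for tr in desc.torsions:
        ph = geometry.dihedral_deg(*(pos[n] for n in tr.atoms))
        t = tr.target if tr.target is not None else ph
        dev = geometry.wrap_periodic_dev(ph, t, tr.period)
        s = tr.sigma if tr.sigma else 15.0
        rows.append(ResidualRow("torsion", tr.atoms, t, ph, dev, dev / s))
    for p in desc.planes:
        pts = np.array([pos[n] for n in p.atoms])
        w = np.array([1.0 / p.sigma_for(n) ** 2 for n in p.atoms])
        normal, centroid = geometry.best_fit_plane(pts, w)
        for n, pt in zip(p.atoms, pts):
            d = float((pt - centroid) @ normal)
            rows.append(ResidualRow("plane", (p.id, n), 0.0, d, d,
                                    d / p.sigma_for(n)))
    for c in desc.chirals:
        vol = chiral_volume(pos[c.centre], pos[c.atom1], pos[c.atom2],
                            pos[c.atom3])
        if c.sign == "positive":
            dev = min(0.0, vol - config.chiral_margin)
        elif c.sign == "negative":
            dev = max(0.0, vol + config.chiral_margin)
        else:
            dev = 0.0
        rows.append(ResidualRow("chirality", (c.centre,) + c.neighbours,
                                {"positive": 1.0, "negative": -1.0,
                                 "both": 0.0}[c.sign], vol, dev,
                                dev / config.chiral_sigma))

    maxima = {}
    for row in rows:
        maxima[row.kind] = max(maxima.get(row.kind, 0.0), abs(row.deviation))
    f, _ = _objective(x, comp)
    return ResidualReport(rows=rows, maxima=maxima, objective=f)


# ---------------------------------------------------------------------------
# PDB output


def write_pdb(desc: MonomerDescription, coords: dict, res_name: Optional[str] = None,
              chain: str = "A", res_seq: int = 1) -> str:
    """Idealized coordinates as HETATM records (occupancy 1.00, B 20.00)."""
    res = (res_name or desc.code or "UNL")[:3]
    lines = []
    for i, (name, atom) in enumerate(desc.atoms.items(), start=1):
        if name not in coords:
            raise CoordinateError(f"no coordinate for atom {name}")
        x, y, z = np.asarray(coords[name], float)
        el = atom.element.upper()
        aname = name if len(name) == 4 else (f" {name:<3s}" if len(el) == 1
                                             else f"{name:<4s}")
        lines.append(
            f"HETATM{i:5d} {aname:<4s}{res:>4s} {chain}{res_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{20.00:6.2f}          "
            f"{el:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"
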