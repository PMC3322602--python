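# Methods

## The restraint model

A dictionary entry describes a compound at one of two levels. A *minimal*
description is the molecular graph — atoms with elements and formal
charges, bonds with orders (`single`, `double`, `triple`, `aromatic`,
`deloc`) — plus atom names and chiral-centre signs. A *complete*
description adds template restraints: target values and standard
deviations for every bond length and bond angle, periodic torsion
restraints, planar groups with per-atom distance sigmas, and chiral
centres. Chirality is encoded geometrically as the sign of the volume
`V = (r₁−r_c)·((r₂−r_c)×(r₃−r_c))` over three *ordered* neighbours of the
centre; `|V| ≤ 0.1 Å³` is treated as degenerate. No 1/6 factor is applied;
the sign, not the magnitude, carries the information.

Edits to a graph are journalled, and every atom keeps a `parent_ref` to
the atom of the pre-edit monomer it descends from (absent exactly for
atoms added during editing). This provenance is what later lets a
composite compound be diffed back into per-monomer modification entries.

### Hydrogens

Hydrogen counts are derived, not drawn: each heavy atom carries
`effective_valence − floor(Σ bond orders)` hydrogens, where aromatic and
delocalized bonds count 1.5 and the formal charge shifts the valence by
its value (N⁺ binds four partners, O⁻ one). New hydrogens are named from
the heavy parent (NZ → HZ1, HZ2, …); surplus hydrogens are removed
highest-name-first, which makes the adjustment deterministic and
idempotent. The valence table covers H, C, N, O, P, S, Se and the
halogens and is a plain extensible map.

## Energy types and the parameter table

An atom's energy type is composed from its element, hybridization (sp
for a triple or two double bonds, sp2 for any double/aromatic bond, else
sp3), ring membership, and hydrogen count — e.g. `C3h2` for a methylene
carbon, `C2r` for a substituted aromatic carbon. A nitrogen with only
single bonds adjacent to a carbonyl is typed sp2 (amide resonance); it is
the one resonance effect the typer knows about.

Bond and angle targets come from a three-level lookup, each level
symmetric under reversal of the key:

1. exact typed entries (Engh & Huber-style peptide values, e.g. amide
   C–N 1.329 ± 0.014 Å);
2. element-pair entries per bond order (C–C single 1.530 Å, C=N 1.280 Å,
   S–S 2.030 Å, …);
3. covalent-radii sums (bonds) or hybridization ideals (angles:
   109.47°/120°/180° by steric number), with every use of this level
   logged.

The table ships as data (`data/parameters.json`), not code. Default
sigmas are 0.02 Å for bonds and 3.0° for angles; dictionaries read with
missing sigmas get the same defaults and a warning.

**Planar-ring angles.** A ring of sp2 atoms with unequal sides cannot
close with every interior angle at 120° (pyridine's two shorter C–N bonds
force the angle at N below 120°). Rather than ship per-ring angle tables,
interior angles of planar rings are taken from the *cyclic polygon* that
realizes the ring's bond targets — the unique inscribed polygon whose
central angles sum to 2π — and exocyclic angles take the symmetric
remainder `(360° − interior)/2`. This makes ring restraints exactly
satisfiable by construction. The price is that the values are geometric,
not spectroscopic: the computed angle at a pyridine-type nitrogen is
slightly above 120° where experiment puts it near 117°. For refinement
purposes internal consistency was preferred over per-compound curation.

### Restraint enumeration

Completion generates one angle per bonded path of length two (so the
angle count equals `Σ_atoms deg(deg−1)/2`), one torsion per central bond
whose ends are non-terminal (end atoms picked by atomic number then name,
so the choice is independent of insertion order; period 2 with a 180°
target between sp2 atoms, else period 3), a planar group per trigonal sp2
atom merged while two groups share at least two atoms (four-coordinate
atoms such as phosphate P never seed a plane), and chiral centres at
four-coordinate atoms with at least three heavy substituents
distinguishable by a one-shell signature. Declared chirality is always
preserved; centres detected from the graph alone get sign `both`, since a
graph does not orient them.

### Descriptions from coordinates

Bond perception connects atoms closer than the covalent-radii sum plus
0.45 Å (pairs closer than 0.5 Å are rejected as overlapping); orders are
then raised greedily, shortest bond first, while both partners have
unused valence; chirality signs are measured from the coordinates. In the
"as-is" mode the observed distances, angles and torsions become the
targets directly, with table-default sigmas — intended for high-precision
input geometry, since every observed value that differs from the standard
target would otherwise surface as a modification edit.

## Idealization

`embed` builds a starting conformation by breadth-first placement from
bond and angle targets with seeded random torsions, with three structural
aids: six-membered saturated rings are placed as ideal chairs (vertex
angles exactly tetrahedral, ring torsions ±60°) and other/planar rings as
regular polygons, oriented to match whatever is already placed; the third
substituent of a trigonal atom completes the plane rather than taking a
free cone position; and candidate torsions are scored by clearance over
topology-aware contact floors, preferring extended growth. Declared
chiral signs are enforced at the start by reflecting the smallest pendant
branch of a mirrored centre.

`regularize` minimizes

    Σ_b (d−d₀)²/σ² + Σ_a (θ−θ₀)²/σ² + Σ_t wrap_p(φ−φ₀)²/σ²
    + Σ_planes Σ_i dist_i²/σ_i² + chirality hinge + contact hinge

with L-BFGS and analytic gradients. The plane in each group is the
weighted best-fit plane of the current coordinates; because the plane
parameters minimize the same sum, the fixed-plane gradient is exact
(envelope theorem). The chirality hinge penalizes the signed volume
quadratically past a ±0.1 Å³ margin on the wrong side and is inactive for
sign `both`. The torsion deviation is wrapped to the nearest of the
`period` equivalent minima.

**The contact term.** Dictionary terms alone leave free torsions able to
fold a molecule onto itself — a folded rotamer can satisfy every bond,
angle and torsion restraint exactly. Since idealized coordinates must
support graph re-perception (and are exported for model building), the
objective includes a one-sided quadratic keeping pairs beyond 1–3
topology outside element-aware floors: 1.6 Å for H–H, 1.7 Å for X–H,
2.2 Å for heavy–heavy (natural 1,3-diaxial H⋯H contacts sit near 1.85 Å,
so the hinges engage only on genuinely folded geometry). Weight is
1/(0.2 Å)², i.e. soft compared to bonds.

Convergence: minimization runs in chunks of 400 iterations (cap 4000) and
stops when the objective falls below 10⁻⁵ (all deviations far below their
sigmas), the gradient below 10⁻⁶, the per-chunk coordinate move below
10⁻⁴ Å, or when the line search makes no further progress at working
precision. A centre that survives minimization with the wrong chiral sign
— inversion crosses an angle-strain barrier a local minimizer will not
climb — is fixed by reflecting the offending branch and re-minimizing (at
most twice). Non-convergence is reported in the residual report, never
raised. All tolerances live on `IdealizerConfig`.

## The link algorithm

`compose` deep-copies the two monomers (which may be two copies of the
same compound) and records the covalent link bond; further editing is
blocked except the link-bond order. Composite atoms receive unique names
(side suffix `1`/`2`, element-keyed counter on overflow), hydrogens are
re-adjusted across the new bond — a valence overflow here is reported
with advice to delete the clashing atom first — the complete description
is generated *from scratch* against the parameter table, and coordinates
are idealized. Regenerating rather than inheriting restraints keeps
modification entries small: targets change only where energy types
change, i.e. near the link.

`split` first moves every restraint that references atoms of both
monomers into the link entry, then diffs each side against its original
monomer via parent references: atoms without a parent are `add` records,
original atoms without a descendant are `delete` records, and surviving
items become `change` records when their type changed, an endpoint atom's
energy type changed, or the target moved by more than the declared sigma
(multiplier configurable, default exactly 1). Restraints that vanish with
a deleted atom are implied and not recorded; plane groups, which only
shrink when a member is deleted, are matched on their surviving-atom sets.
The inverse operations `apply_modification` (delete → change → add) and
`apply_link` (modified A ∪ modified B ∪ link restraints, side-qualified
naming) reproduce the regularized composite exactly — atoms, bonds,
targets — which the test suite asserts on dozens of random compositions.

`save_additional_library` writes modification list + link list + the two
modifications + the link; a monomer block is included only when its code
does not resolve in the declared base library, and a shadowing warning is
raised when a written code collides with a base entry (an additional
library entry silently overrides the standard one of the same name during
refinement — easy to do by accident, hard to notice).

## The dictionary CIF dialect

Reading goes through gemmi's CIF parser; unknown categories are carried
as opaque payload so foreign entries round-trip. Writing is deterministic:
comp list, mod list, link list (each only when non-empty; an empty CIF
loop is not syntactically expressible), then entries in insertion order;
distances at 3 decimals, angles at 2; values quoted only when needed.
`write ∘ read ∘ write` is byte-identical, and reading back a written
library reproduces it entry for entry. Additional-library files produced
by save-as-link carry monomer blocks without a comp list. Chirality signs
serialize as `positiv`/`negativ`/`both`.

## LINK-record surveys

`LINK` lines are parsed by PDB v3.3 fixed columns; `LINKR` (the
refinement dialect) shares the atom/residue columns and carries a
dictionary link id in the trailing field. For amino–amino surveys,
records where both atoms are backbone C/N, or both are CYS SG, are
excluded as artefacts of how depositions annotate the polymer backbone
and disulfides. Linkage types are counted on the lexicographically sorted
(residue, atom) pair, so swapped record sides tally together. The
amino-acid code set (20 standard + MSE + D-forms) is configurable.

## The fragment set

The built-in library holds hand-encoded standard chemistry: glycine,
alanine, cysteine, lysine (ammonium side chain, +1), pyridoxal-5′-
phosphate with its aldehyde oxygen, and α-D-glucopyranose, plus generic
modifications (carboxyl-terminus deletion, amino-group deprotonation,
thiol/anomeric/hydroxyl deletions) and links (trans-peptide, disulfide,
α/β 1→4 glycosidic). Chirality signs were frozen from MMFF-optimized
reference conformers of the L-amino acids and α-D-glucose. The set is
deliberately small and regular: it exercises every code path (aromatic
and saturated rings, hypervalent phosphorus, charged nitrogen, sulfur,
stereocentres, all three link flavours) but does not emulate the
long-tail irregularities of a full monomer library — alternate
protonation states, metals, deloc ring systems beyond Kekulé, or
curated per-compound torsion values. Tests passing on these fragments
demonstrate the machinery, not coverage of all deposited chemistry.

`random_molecule` grows a random tree over {C, N, O, S} under the valence
model, promotes a few bonds to double, and fills hydrogens; it is the
workhorse for enumeration oracles and round-trip property tests.

## Problem sizes

The shipped computations run at dictionary scale: molecules of 10–60
atoms, idealizations over a handful of seeds per compound, 25–50 random
compositions in the round-trip checks, and 100 random molecules in the
enumeration oracle. These sizes were chosen as representative of
dictionary work, where compounds rarely exceed ~100 atoms.

## Known limitations

- Aromaticity is taken from declared bond orders; no perception from
  Kekulé patterns or rings.
- The amide rule is the only resonance correction in energy typing.
- Planar-ring angle targets are geometric (cyclic polygon), not fitted to
  small-molecule statistics.
- Stereochemistry is limited to the three-neighbour chiral-volume model:
  no E/Z bond descriptors, no atropisomers.
- Graph perception from coordinates trusts the covalent-radii window and
  can mis-bond very distorted inputs; no accuracy claim is made for
  low-precision coordinates.
- Fused-ring systems are embedded ring-by-ring from a cycle basis; heavily
  bridged polycyclics may need more minimization than the defaults allow.
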