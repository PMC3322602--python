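# linksmith

Tools for building **template-restraint dictionaries** for macromolecular
refinement: monomer descriptions, modification entries, and covalent link
entries in the CCP4 monomer-library CIF dialect.

Crystallographic refinement programs restrain model geometry to dictionary
targets: bond lengths and angles with standard deviations, torsion angles
with periodicity, planar groups, and chiral centres encoded as the sign of
the volume `V = det[r₁−r_c, r₂−r_c, r₃−r_c]` over three ordered
neighbours of a centre. A compound that appears covalently bound to
another — a glycosylated side chain, a disulfide bridge, a cofactor fused
to a lysine — needs more than two monomer entries: it needs restraints for
the new bond and for everything that changes around it. Dictionaries store
this economically as two *modification* entries (the edits to each
monomer) plus one *link* entry (the cross-monomer restraints), so that
describing all polypeptides of 20 amino acids in three chain positions and
two conformations takes 24 entries instead of 120.

`linksmith` implements that machinery end to end:

- **`cif_io`** — read/write the dictionary dialect (`data_comp_list`,
  `data_mod_*`, `data_link_*` blocks), with deterministic, byte-stable
  output and additional-over-standard precedence on merge.
- **`molgraph`** — the molecular-graph model: journalled edits with
  parent-atom provenance, automatic hydrogen bookkeeping from valence,
  signed chiral volumes, integrity validation.
- **`completion`** — minimal → complete descriptions: atom energy types
  from element/hybridization/H-count/ring membership, restraint
  enumeration (angles per bonded path, torsions per central bond, sp2
  planes, stereocentre detection), target lookup in an Engh & Huber-style
  parameter table; plus graph perception from coordinates and an "as-is"
  mode that takes targets from observed geometry.
- **`idealizer`** — coordinates satisfying a complete description:
  seeded breadth-first embedding (ring templates, trigonal completion)
  followed by L-BFGS minimization of the weighted restraint objective
  with analytic gradients.
- **`linkgen`** — the link generator: compose two monomers with a covalent
  bond, regularize the composite, and split it into two modifications plus
  one link; `apply_modification`/`apply_link` invert the process exactly.
- **`pdblinks`** — PDB-header `LINK`/`LINKR` record parsing, the
  amino–amino artefact filter (backbone C–N and CYS SG–SG pairs), and
  linkage-type tallies.
- **`fixtures`** — a built-in fragment library (GLY, ALA, CYS, LYS,
  pyridoxal-5′-phosphate, α-D-glucopyranose, generic peptide/disulfide/
  glycosidic mods and links), a random-molecule generator, and the
  library-design entry counter.

## Worked example: a Schiff-base link

Pyridoxal-5′-phosphate (PLP) binds as an internal aldimine: the lysine NZ
condenses with the PLP aldehyde carbon C4A, losing the aldehyde oxygen.
Building the dictionary entries for refinement of such a structure:

```python
from linksmith import (builtin_fragments, compose, regularize_session,
                       save_additional_library, apply_edit, GraphEdit)

lib = builtin_fragments()
lys, plp = lib.monomers["LYS"], lib.monomers["PLP"]

# delete the aldehyde oxygen, then draw the Schiff-base double bond
plp_edited = apply_edit(plp, GraphEdit("delete_atom", {"name": "O4A"}))
session = compose(lys, plp_edited, ("NZ", "C4A", "double"),
                  original_a=lys, original_b=plp)
regularize_session(session, seed=1)
out_lib, text = save_additional_library(session, base_library=lib)
```

which prints (via the session report and the returned library):

```
converged: True
max |bond dev|:  0.0005 A
max |angle dev|: 0.15 deg
automatic H edit (side 1): delete_atom HZ2
automatic H edit (side 1): delete_atom HZ3
data blocks: ['mod_list', 'link_list', 'mod_LYSmod1', 'mod_PLPmod1', 'link_LYS-PLP']
link bond: NZ(LYS)=C4A(PLP) double, target 1.280 A
```

Reading the output: the composite idealized to sub-millangstrom bond
residuals; two of the three ammonium hydrogens on NZ were removed
automatically when the new double bond consumed the nitrogen's valence
(the remaining proton keeps the aldimine nitrogen cationic); and the saved
additional library holds exactly five data blocks — the modification and
link lists, one modification per monomer, and the link carrying the new
C4A=NZ bond restrained to 1.28 Å. Because both parent monomers resolve in
the base library, no `data_comp_` block is written, so free PLP elsewhere
in a structure keeps its standard description.

The same workflow from the shell:

```sh
linksmith make-link --comp1 LYS --comp2 PLP --delete 2:O4A \
    --bond 1:NZ 2:C4A=double --out lys-plp.cif --seed 1
```

Other subcommands: `linksmith idealize` (write idealized coordinates as
PDB), `linksmith complete` (minimal → complete entry), `linksmith perceive
[--as-is]` (description from coordinates), `linksmith apply-mod`, and
`linksmith survey-links` (LINK-record tallies as TSV).

## Documentation

`docs/methods.md` describes the restraint model, the idealizer's objective
and its numerical choices, the parameter table, what the built-in fragment
set does and does not emulate, and known limitations.
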