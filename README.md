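# xtalmol

Derive chemical entities — bonds, bond orders, Kekulé forms, formal
charges and metal-coordination conventions — from small-molecule
crystallographic data.

The pipeline:

1. **`cif_io`** — parse a single-data-block CIF dialect (cell, symmetry
   operators as `x,y,z` strings, atom sites with occupancies, disorder
   labels and attached-hydrogen counts, declared formula, provenance).
2. **`ensemble`** — expand the asymmetric unit over the symmetry
   operators, merge special positions, resolve positional disorder to one
   representative conformation (highest summed occupancy, then most atoms,
   then lexicographically lesser group name), trace covalent networks
   across lattice translations (flagging polymers), and reduce to a
   minimal stoichiometrically correct grouping of crystallographically
   independent entities.
3. **`perception`** — the six-step structure assignment: connectivity from
   covalent radii, a preflight screen for steric clashes and exceeded
   valences, zero-order coordination bonds for every metal contact
   (hapticity falls out naturally), unambiguous higher-order bonds,
   length-driven functional-group templates (azide, nitro, carboxylate,
   sulfonate, phosphate, nitrile, isocyanide), Kekulé assignment by
   exhaustive perfect-matching search minimizing summed squared
   bond-length z-scores (avoiding formal-charge introduction first), and
   formal charges with zero-order bonds excluded from the bookkeeping.
4. **`validation`** — six geometry checks (pi-electron count, bond
   geometry, bond length by the 3-sigma rule, radicals, atom charges,
   ensemble charge) and six entry-level quality tests (structure, formula
   compatibility, provenance, compositional disorder, maintainer markup,
   manual review). Failing entries are marked, never dropped.
5. **`output`** — MDL Molfile V2000 (zero-order bonds as type 8, 999-atom
   limit) and V3000 (type 9, unlimited), SDF with `COD_SDF_ISSUES` /
   `COD_SDF_VALIDITY_STATUS` data items, TSV with optional column-header
   or DataWarrior-style headers (`C1-Problems`, `Is valid entry` columns),
   and three-scope SMILES (crystal / components / ligands) with
   coordination bonds converted to single bonds or stripped.
6. **`chem_tables`** — element properties (`data/elements.yaml`) and the
   Gaussian bond-length class table (`data/bond_classes.tsv`).
7. **`fixtures`** — deterministic synthetic structures (benzene,
   ferrocene, azides, ionic pairs, rock salt, a 1-D polymer chain, and
   deliberately defective entries) used by the tests and the CLI.

## CLI

```sh
# emit the bundled fixture set as CIF files
xtalmol fixtures --out-dir fixtures

# perceive chemistry -> SDF on stdout (+ run report on stderr)
xtalmol perceive fixtures/ferrocene.cif

# TSV / DataWarrior-style output, V3000, SMILES scopes
xtalmol perceive --tsv-output --print-dwar-header fixtures/benzene.cif
xtalmol perceive --v3000 fixtures/ferrocene.cif
xtalmol perceive --smiles-output --smiles-scope ligands fixtures/ferrocene.cif

# per-entry validity verdicts, one criterion per column
xtalmol validate fixtures/*.cif
```

Per-entry perception parameters (tolerances, cutoffs, atom limits) can be
supplied as a YAML mapping via `--config`.

## Conventions and caveats

- Metal atoms are the atomic-number set
  [3,4] ∪ [11,13] ∪ [19,31] ∪ [37,51] ∪ [55,84] ∪ [87,103]; every bond
  touching one becomes a zero-order coordination bond, ignored when
  assigning formal charges (so e.g. ferrocene is Fe²⁺ plus two C₅H₅⁻
  rings, each with one carbanion carbon).
- The bundled bond-class table is rebuilt from standard reference bond
  lengths with a two-number pi-context key; it preserves the schema and
  Gaussian semantics of corpus-derived distribution sets but not their
  exact values.
- Attached hydrogens contribute to valences and formulas but never appear
  as explicit atoms in output.
- The SMILES writer is a minimal deterministic non-stereo grammar; it does
  not aim to match any external canonicalization.
- Maintainer markup is read from `_cod_duplicate_entry`,
  `_cod_suboptimal_structure`, `_cod_theoretical_structure` and
  `_cod_manual_exclusion` items (a documented dialect).
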