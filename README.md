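# gpcrgraft

Multi-template chimeric homology modeling for 7TM receptors, plus the
bioactivity curation that goes with structure-based ligand work.

## The problem

Most G protein-coupled receptors still lack an experimental structure, so
virtual screening, binding-site analysis and molecular dynamics lean on
homology models. A single-template model wastes experimental information:
the best template for the bulk of the transmembrane bundle is rarely the
best template for every helix end, loop, or helix bulge, and crystallised
constructs carry fusion artifacts, engineered mutations and missing
segments. `gpcrgraft` implements the alternative strategy: cover as much of
the target as possible with *experimental* coordinates by combining a ranked
main template with alternative local templates, grafted onto anchor
residues, and by re-typing sidechains from a position-specific rotamer
library so that far more residues rest on an identical, experimentally
observed amino acid.

Residue correspondence throughout uses structure-based generic residue
numbers (`3x50` is the reference position of TM3; `45x50` the conserved
ECL2 cysteine between TM4 and TM5), which make residues comparable across
receptors and anchor every alignment and graft.

## What the pipeline does

1. **Main-template ranking** — lexicographic on (i) receptor class with the
   fixed fallbacks B2→B1 and Taste2→A, (ii) activation state
   (inactive/intermediate/active, consumed as an annotation), (iii)
   sequence similarity over generic-numbered positions, (iv) structure
   coverage (generic positions with backbone coordinates), (v) resolution.
2. **Trimming** — distorted regions and helix residues the target does not
   have are removed from the main template.
3. **Helix-end extension** — a local donor is superposed on the last
   retained helical turn (4 residues, backbone atoms N/CA/C/O) and only the
   residues beyond the anchor are copied.
4. **Loop grafting** — donors chosen by length (exactly the target's residue
   count), similarity, coverage and resolution, superposed on the two
   terminal residues of each flanking helix. ECL2 is special-cased: two
   halves anchored on the conserved 45x50 cysteine backbone, which is
   itself inferred from a donor (superposed on the last TM4 residue, the
   first TM5 residue and the TM3 cysteine 3x25) when the main template
   lacks it.
5. **Bulge/constriction swaps** — helix windows where target and template
   disagree on a π-bulge or 3₁₀ constriction are replaced from a donor with
   the target's configuration.
6. **Rotamers** — a position-specific library harvested from all catalog
   structures re-types non-conserved sidechains to the target's amino acid
   by N/CA/C frame superposition (backbone untouched), and reverts
   engineered construct mutations to wildtype.
7. **Disulphides** — the cross-class 3x25–45x50 bridge (plus optional
   extra pairs) is closed by a CA–CB torsion scan to SG–SG ≈ 2.05 Å.
8. **Remainder** — anything still untemplated is exported as a PIR
   alignment + template PDB for an external comparative-modeling builder,
   or filled with a clearly flagged linear CA trace so the pipeline runs
   end to end self-contained.
9. **Evaluation** — region-wise backbone RMSD (overall / 7TM / ligand site
   / ECL2) after a single 7TM superposition, restricted to residues present
   in all compared models.

A bioactivity module curates ChEMBL-style records: validity filtering with
reason codes, and non-redundant min/max/mean summaries per
ligand–receptor–species triad on the pChEMBL scale (p = 9 ⇔ 1 nM), with
chemical-property and vendor filters and SMILES/CSV export.

Because the real structure corpus is not shippable, the package includes a
first-class synthetic generator: ideal-geometry 7TM toy receptors
(1.5 Å rise, 100° twist, antiparallel bundle) with generic numbering,
planted conserved cysteines, and controlled defects with truthful
annotations — so every geometric contract is testable against an exact
ground truth.

## Worked example

Generate a multi-defect scenario (an intact target receptor; a main
template missing six helix ends, four loops and carrying an engineered
mutation; five specialist donors), build the chimera, and evaluate it
against the known ground truth:

```bash
gpcrgraft make-fixtures --preset multi-defect --seed 3 --out fx/
gpcrgraft build-model --catalog fx/manifest.json --target fx/target.json \
    --state inactive --out models/
gpcrgraft evaluate --model models/target.model.pdb --reference fx/reference.pdb
```

which prints (stderr line from the build, stdout table from the evaluation):

```
target: main=MAIN01 identity 98.4% -> 99.5%
region        n_residues  backbone_rmsd
overall       182         0.000
7TM           140         0.000
ECL2          9           0.000
ligand_site   4           0.000
```

Reading: the main template covered the bundle at 98.4% identity; rotamer
application raised the chimeric template to 99.5%. Every grafted segment was
rebuilt from an intact-twin donor, so all regions superpose onto the ground
truth at 0.000 Å — on ideal toys, grafting is exact by construction, and any
nonzero value would indicate an anchoring error. `models/target.report.json`
records per-segment donors, anchor RMSDs, reverted mutations, the
3x25–45x50 disulphide distance and any unmodeled stretches.

The same workflow from Python:

```python
from gpcrgraft import ToySpec, generate_toy_receptor, build_chimera

truth, target, _ = generate_toy_receptor(ToySpec(seed=3))
# catalog: list of (AnnotatedStructure, TemplateAnnotation)
chimera, provenance, report = build_chimera(target, catalog, "inactive")
```

For the ligand side:

```bash
gpcrgraft ligands demo-data --n 1000 --violation-rate 0.1 --seed 4 --out lig/
gpcrgraft ligands filter --in lig/activities.csv \
    --out-kept kept.csv --out-dropped dropped.csv   # kept 900, dropped 100
gpcrgraft ligands aggregate --in kept.csv --out triads.csv
```

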