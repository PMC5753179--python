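# Methods

This note documents the models, conventions and numerical choices behind
`gpcrgraft`, what the synthetic test bed does and does not emulate, and the
known limitations.

## Residue correspondence

All cross-structure bookkeeping is keyed on structure-based generic residue
numbers (the "x" scheme): one token per class-wide position, `<code>x<NN>`,
with one-digit codes for TM1–TM7 and H8 and two-digit codes for the loops
(12 = ICL1, 23 = ECL1, 34 = ICL2, 45 = ECL2, 56 = ICL3, 67 = ECL3). A
three-digit suffix (`5x461`) marks a bulge insertion after the two-digit
parent position and sorts between its neighbours. The sequence-based dot
scheme is out of scope. Alignments pair residues sharing a token; an
un-numbered stretch caught between two shared anchors is paired outside-in
from both anchors with surplus residues gapped at the stretch centre, so
both anchors always survive. Identity and similarity are percentages over
aligned (both-sides non-gap) columns; similarity counts strictly positive
BLOSUM62 scores. BLOSUM62 is a convention, not a claim — the matrix is an
argument everywhere it is used.

## Template ranking

Candidates are ordered lexicographically on: class rank under the fixed
fallback map (B2 accepts B1, Taste2 accepts A, every other class only
itself), activation-state match (the state is an input annotation derived
upstream from TM5/TM6 displacement; it is never computed here), sequence
similarity, structure coverage (count of generic positions with a complete
N/CA/C/O backbone), and resolution. The criteria are unweighted by design:
the list order is the priority order. Two numerical choices make the order
reproducible: similarity is compared at 0.1-percentage-point granularity so
float noise cannot reorder near-ties, and exact ties fall back to the
structure id (ascending). If no eligible-class template exists in the
desired activation state the selection fails loudly rather than silently
substituting a different state. Local (per-segment) templates are ranked by
similarity, coverage and resolution among candidates with a complete
backbone for the segment; loop donors must additionally match the target's
loop length exactly (an opt-out flag relaxes this), and "no survivor" is a
valid outcome that routes the segment to remainder modeling.

## Superposition

Rigid-body fits use the Kabsch solution: SVD of the covariance of the
centred point sets with a determinant sign correction, so reflections are
never returned. All points are weighted equally. Fits require ≥ 3 points
and fail with a conditioning error when the reference is (near-)collinear,
because the rotation about the line is then undetermined. Orthonormality
and exact-recovery tolerances on clean inputs are 1e-9. The test suite
cross-checks the implementation against an independent solver and against
brute-force random placements.

## Grafting

The chimera is assembled in target numbering (author number = 1-based
target index), with residue correspondence by generic position. Anchors are
always backbone heavy atoms (N/CA/C/O) and anchor residues always keep
their pre-graft coordinates — grafts copy only non-anchor residues, and
when donor and model anchors already coincide the transform short-circuits
to the exact identity, which makes intact-twin recovery bit-exact.

Quantified conventions (the underlying protocol does not fix counts):

* a "helical turn" anchor is 4 residues (one α-turn ≈ 3.6, rounded up);
* loop anchors are 2 residues per flanking helix;
* ECL2 is grafted as two halves: first half anchored on the TM4 terminal
  2 residues plus the 45x50 backbone, second half on 45x50 plus the TM5
  first 2 residues; when the model lacks 45x50 it is first inferred from a
  donor superposed on the last TM4 residue, the first TM5 residue, and the
  TM3 cysteine 3x25;
* bulge/constriction swap windows extend one residue either side of the
  mismatched parent position and are anchored on 2 residues per side; the
  donor must carry exactly the target's token configuration in the window;
* an anchor fit worse than 2.0 Å flags the grafted residues
  (`low_confidence`) but does not reject the graft.

Helix extensions run before loop grafts (fixed order; the loop anchors then
sit on already-repaired helix ends). Any stage failure downgrades its
segment to "unmodeled" instead of aborting — a partial model with complete
provenance is always produced, which is the right trade-off for a pipeline
meant to cover a whole receptor family. Every chimera residue has exactly
one backbone source; unmodeled stretches are listed explicitly, never
silent.

## Rotamers

The library holds one entry per (structure, generic position, amino acid)
with a complete N/CA/C frame and a non-empty sidechain containing CB;
glycines are excluded. The donor frame is N/CA/C — O is excluded because it
moves with ψ and would contaminate the frame. Application superposes the
donor frame onto the acceptor residue's frame and replaces only sidechain
atoms; backbone coordinates are untouched to the last bit. Among several
entries the donor from the highest-ranked source (template-selection order
relative to the target) wins. Mutation reversion re-types each annotated
construct position to wildtype through the same path; positions without a
library entry are flagged, never skipped silently. Steric clashes
(inter-residue heavy-atom pairs < 2.0 Å, residues ≥ 2 apart in sequence)
are detected and counted but deliberately not re-modeled — that is
remainder-stage work. Completeness checking does not enforce canonical
per-amino-acid atom sets (the toy corpus uses simplified sidechains), so
partially resolved sidechains in real structures would need upstream
filtering.

## Disulphides

The cross-class bridge 3x25–45x50 is always attempted; the class-A ECL3
bridge (two ECL3 cysteines, or ECL3 to the top of TM6) enters through
explicit extra pairs since its position varies. Both target positions must
be cysteine — anything else is a warning and a skip, because many receptors
genuinely lack the bridge. Construction rotates each cysteine's SG about
its CA–CB axis on a 5° grid (joint scan over both angles) to the pair
minimising |SG–SG − 2.05 Å|; the bridge is recorded only if the result
lands in [1.9, 2.2] Å. With the toy geometry an exact 2.05 Å solution
exists by construction, and the 5° grid stays within the band
(worst-case discretisation error ≈ 0.15 Å on circles of radius 1.69 Å).

## Remainder

Untemplated stretches are exported as a PIR alignment (target row full
sequence, template row gapped at unmodeled indices, equal lengths) plus the
chimera PDB — valid input for a standard comparative-modeling run; no
external builder is re-implemented or invoked. The built-in filler is
deliberately naive: CA positions linearly interpolated between flanking
anchors (terminal stretches extended along the last chain direction at
3.8 Å per residue), N/C placed off the local tangent, and everything it
invents flagged `low_confidence`. The invariant is that the final model
contains no unflagged invented coordinates.

## Evaluation

One global superposition on the backbone heavy atoms of the common 7TM
positions, then per-region RMSD without re-fitting — so local errors in
loops or the binding site are exposed rather than absorbed into the fit
(per-region re-fitting is available behind a flag). When several models are
compared, all calculations are restricted to generic positions with
complete backbone in every model. The ligand site is defined as positions
whose CA lies within 5 Å of any reference ligand heavy atom, or an explicit
user-supplied set; with no ligand and no set, the region is omitted with a
note.

## Bioactivity curation

Records are dropped, each with a reason code, when the pChEMBL value is
absent, the assay type is neither binding nor functional, or a
data-validity/activity comment matches the configured disqualifying term
list (the shipped default mirrors the upstream database's published
validity categories; the list is a config file, not code). Aggregation is
per (ligand, target, species) triad: min/max/arithmetic-mean on the p
(log) scale; nanomolar columns are derived from the p extremes
(nM-min ↔ p-max) and never averaged on the linear scale. Raw records are
aggregated directly, without pre-averaging within assays. Species is a
free-text key; no taxonomy resolution. Multiple measurements of one triad
in one assay count as separate records.

## The synthetic test bed

The toy generator emulates exactly the inputs the pipeline consumes:
7 ideal α-helices (1.5 Å rise, 100° twist, CA at 2.3 Å from the axis —
consecutive CA–CA ≈ 3.83 Å), arranged antiparallel on an 11 Å circle with
smooth Bézier loop arcs, a short horizontal H8, two-residue un-numbered
termini, simplified sidechains (full heavy-atom sets only for C/K/L/R, CB
plus a pseudo-CG otherwise), and an optional pseudo-ligand near the
extracellular face. Generic numbers put x50 at each helix midpoint; the
one deliberate exception is the extracellular terminal residue of TM3,
which carries the token 3x25 so the conserved disulphide topology of the
real scheme is reproduced (a 20-residue helix centred on x50 cannot
contiguously reach x25). The ECL2 path routes through a cysteine planted
atop TM3 with CB–CB geometry that admits an exact 2.05 Å bridge. Loop and
terminal backbones place N and C off the local tangent so N/CA/C frames are
never collinear.

Defects are applied with truthful annotations. Bulges and constrictions
are *local*: the window is re-laid on an outward arc between fixed flank
residues, so a bulged and a bulge-free twin share every coordinate outside
the window — this is what makes swap recovery exactly testable. Crystal
artifact defects (truncation, segment deletion, distortion, dropped
sidechains, engineered mutations) change the structure but not the
receptor sequence; `diverge` re-types random positions in both and models
a genuinely different receptor. Everything is deterministic per seed.

What passing on toys does and does not show: anchored grafting, provenance,
ranking, rotamer placement and the evaluation protocol are exercised
exactly, because intact twins make recovery errors exactly zero and any
deviation indicates a bookkeeping or anchoring bug. The toys do not test
robustness to real crystallographic noise, non-ideal helices, alternate
conformations, insertion codes, or genuinely ambiguous loop alignments —
on real data anchor RMSDs are nonzero and the 2.0 Å warning gate, rather
than the exactness, is the operative safeguard.

## Problem sizes

The default toy has 186 residues (7×20 TM, 34 loop, 8 H8, 4 termini). The
shipped verification script uses 100 point clouds × 1000 random placements
for superposition optimality, 15 defect scenarios for graft recovery, 50
randomized builds for identity monotonicity, 200 random candidate sets for
ranking, and 1000 synthetic activity records — sizes chosen so the whole
script completes in well under a minute on one core while every check still
has teeth.

## Known limitations

* PDB only (no mmCIF); first model of multi-model files; insertion codes
  pass through untested; altloc policy is highest-occupancy-tie-first.
* N- and C-terminal domains are never templated — they go to remainder
  export or the flagged filler.
* The rotamer library has no backbone-dependent statistics or energy
  scoring; clash handling is detection-only.
* Identity/similarity are computed over aligned generic-numbered positions,
  which is the modeled region — full-sequence identity would differ for
  receptors with long termini.
* Activation states are consumed as annotations; nothing here classifies
  states from coordinates.
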