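"""Chimeric-template assembly.

An incomplete or locally distorted main template is complemented with
alternative local templates: non-native parts are trimmed, helix ends are
extended from donors superposed on the last retained helical turn, loops
are grafted anchored on the adjacent helix ends (ECL2 in two halves around
the conserved 45x50 cysteine), helix bulge/constriction mismatches are
swapped from a donor with the target's configuration, sidechains are
re-typed from the position-specific rotamer library, and the conserved
disulphide bridges are closed.  Every residue of the resulting chimera
carries backbone and sidechain provenance; stages that fail downgrade their
segment to "unmodeled" rather than aborting, so a partial model is always
produced.

The chimera lives in target numbering: author numbers are the 1-based
indices of the target sequence, and residue correspondence is by generic
position throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import RigidTransform, superpose
from .rotamers import (
    apply_rotamer,
    build_library,
    chimeric_identity,
    detect_clashes,
    revert_construct_mutations,
)
from .templates import (
    CatalogEntry,
    rank_main_templates,
    select_segment_template,
    structure_coverage,
)
from .alignment import align_by_generic
from .types import (
    AlignmentError,
    AnnotatedSequence,
    AnnotatedStructure,
    BACKBONE_ATOMS,
    GenericPosition,
    GraftError,
    HELIX_SEGMENTS,
    InvariantError,
    LOOP_FLANKS,
    ResidueRecord,
    SwapError,
    TemplateAnnotation,
    TM_SEGMENTS,
    sort_generic,
)

GRAFT_KINDS = ("helix_extension", "loop", "ecl2_half", "bulge_swap", "constriction_swap")

#: a "helical turn" for anchoring purposes: 4 residues (one alpha turn,
#: 3.6 residues, rounded up)
TURN_RESIDUES = 4
#: loop anchors: 2 residues per flanking helix
LOOP_ANCHOR_RESIDUES = 2
#: anchor-fit quality gate (warning, not rejection)
ANCHOR_WARN_RMSD = 2.0

SS_TARGET = 2.05          # ideal disulphide S-S bond length, Å
SS_RANGE = (1.9, 2.2)
SS_SCAN_STEP_DEG = 5.0


@dataclass(frozen=True)
class GraftSpec:
    segment: str
    donor_structure: str
    donor_residue_range: tuple[str, str]
    anchor_set: tuple[tuple[str, tuple[str, ...]], ...]
    kind: str
    anchor_rmsd: float = 0.0
    warning: bool = False

    def __post_init__(self) -> None:
        if self.kind not in GRAFT_KINDS:
            raise InvariantError(f"unknown graft kind {self.kind!r}")
        if not self.anchor_set:
            raise InvariantError("anchor_set must be non-empty")
        for _, atoms in self.anchor_set:
            if any(a not in BACKBONE_ATOMS for a in atoms):
                raise InvariantError("anchors restricted to backbone heavy atoms")


@dataclass
class ProvenanceEntry:
    backbone_source: str = "unmodeled"
    sidechain_source: str = "target-placeholder"
    original_aa: Optional[str] = None


@dataclass
class ProvenanceMap:
    """Per-residue backbone/sidechain source, keyed by target index."""

    entries: dict[int, ProvenanceEntry] = field(default_factory=dict)

    def set_backbone(self, index: int, source: str, original_aa: str) -> None:
        e = self.entries.setdefault(index, ProvenanceEntry())
        e.backbone_source = source
        e.sidechain_source = source
        e.original_aa = original_aa

    def set_sidechain(self, index: int, source: str) -> None:
        self.entries.setdefault(index, ProvenanceEntry()).sidechain_source = source

    def backbone_sources(self) -> set[str]:
        return {
            e.backbone_source
            for e in self.entries.values()
            if e.backbone_source != "unmodeled"
        }

    def original_aa_map(self) -> dict[int, str]:
        return {
            i: e.original_aa
            for i, e in self.entries.items()
            if e.original_aa is not None
        }


@dataclass
class BuildReport:
    target: str
    desired_state: str
    main_template: str = ""
    ranked_templates: list[str] = field(default_factory=list)
    segment_sources: dict[str, str] = field(default_factory=dict)
    grafts: list[GraftSpec] = field(default_factory=list)
    trimmed_residues: list[str] = field(default_factory=list)
    rotamers_applied: int = 0
    rotamer_fallbacks: list[str] = field(default_factory=list)
    mutation_reversions: list[tuple[str, Optional[str]]] = field(default_factory=list)
    disulphides: list[tuple[str, str, float]] = field(default_factory=list)
    raw_identity_pct: float = 0.0
    chimeric_identity_pct: float = 0.0
    unmodeled_stretches: list[tuple[str, int, int]] = field(default_factory=list)
    clashes: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "target": self.target,
            "desired_state": self.desired_state,
            "main_template": self.main_template,
            "ranked_templates": self.ranked_templates,
            "segment_sources": self.segment_sources,
            "grafts": [
                {
                    "segment": g.segment,
                    "donor": g.donor_structure,
                    "range": list(g.donor_residue_range),
                    "kind": g.kind,
                    "anchor_rmsd": g.anchor_rmsd,
                    "warning": g.warning,
                }
                for g in self.grafts
            ],
            "trimmed_residues": self.trimmed_residues,
            "rotamers_applied": self.rotamers_applied,
            "rotamer_fallbacks": self.rotamer_fallbacks,
            "mutation_reversions": [list(m) for m in self.mutation_reversions],
            "disulphides": [list(d_) for d_ in self.disulphides],
            "raw_identity_pct": self.raw_identity_pct,
            "chimeric_identity_pct": self.chimeric_identity_pct,
            "unmodeled_stretches": [list(s) for s in self.unmodeled_stretches],
            "clashes": self.clashes,
            "warnings": self.warnings,
        }
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class BuildOptions:
    strict_loop_length: bool = True
    anchor_warning_rmsd: float = ANCHOR_WARN_RMSD
    extra_disulphide_pairs: tuple[tuple[str, str], ...] = ()
    apply_rotamers: bool = True
    revert_mutations: bool = True


# --- helpers ----------------------------------------------------------------


def _segment_tokens(target: AnnotatedSequence, segment: str) -> list[GenericPosition]:
    toks = [r.generic for r in target.segment_residues(segment) if r.generic is not None]
    return sort_generic(toks)


def _target_index(target: AnnotatedSequence, generic: GenericPosition) -> int:
    return target.by_generic()[generic].index


def _anchor_coords(
    residues: Sequence[ResidueRecord], atoms: Sequence[str] = BACKBONE_ATOMS
) -> np.ndarray:
    return np.concatenate([r.backbone_coords(atoms) for r in residues])


def _copy_residue_into(
    model: AnnotatedStructure,
    donor_res: ResidueRecord,
    target_index: int,
    generic: GenericPosition,
    transform: Optional[RigidTransform],
    warn: bool,
) -> None:
    atoms = {
        name: (xyz.copy() if transform is None else transform.apply(xyz))
        for name, xyz in donor_res.atoms.items()
    }
    rec = ResidueRecord(
        chain="A",
        author_number=target_index,
        amino_acid=donor_res.amino_acid,
        generic=generic,
        atoms=atoms,
        flags={"low_confidence"} if warn else set(),
    )
    by_author = model.by_author()
    if target_index in by_author:
        model.residues.remove(by_author[target_index])
    model.residues.append(rec)
    model.sort_residues()


def _superpose_on_anchors(
    model: AnnotatedStructure,
    donor: AnnotatedStructure,
    anchor_tokens: Sequence[GenericPosition],
) -> tuple[RigidTransform, float]:
    m_by = model.by_generic()
    d_by = donor.by_generic()
    for g in anchor_tokens:
        if g not in d_by or not d_by[g].has_backbone:
            raise GraftError(f"donor {donor.id} lacks anchor position {g}")
        if g not in m_by or not m_by[g].has_backbone:
            raise GraftError(f"model lacks anchor position {g}")
    ref = _anchor_coords([m_by[g] for g in anchor_tokens])
    mob = _anchor_coords([d_by[g] for g in anchor_tokens])
    if np.allclose(mob, ref, atol=1e-12):
        return RigidTransform.identity(), 0.0
    return superpose(mob, ref)


# --- stage operations -------------------------------------------------------


def trim_nonnative(
    main: AnnotatedStructure,
    annotation: TemplateAnnotation,
    target: AnnotatedSequence,
) -> tuple[AnnotatedStructure, list[str]]:
    """Remove distorted regions and helix positions the target lacks.

    Returns a trimmed copy and the log of removed residue descriptors.
    Trimming that would leave a TM helix with fewer than 4 residues is an
    integrity error.
    """
    if annotation.structure_id != main.id:
        raise GraftError(
            f"annotation {annotation.structure_id} does not belong to {main.id}"
        )
    out = main.copy()
    removed: list[str] = []

    distorted: set[tuple[str, float, float]] = set()
    for rng in annotation.distorted_ranges:
        lo = GenericPosition.from_token(rng.first).ordinal
        hi = GenericPosition.from_token(rng.last).ordinal
        distorted.add((rng.segment, lo, hi))

    target_tokens = {r.generic for r in target.residues if r.generic is not None}

    keep: list[ResidueRecord] = []
    for r in out.residues:
        drop = False
        if r.generic is not None:
            o = r.generic.ordinal
            for seg, lo, hi in distorted:
                if r.generic.segment == seg and lo <= o <= hi:
                    drop = True
                    break
            if (
                not drop
                and r.generic.segment in HELIX_SEGMENTS
                and r.generic not in target_tokens
            ):
                drop = True
        elif "distorted" in r.flags:
            drop = True
        if drop:
            removed.append(
                r.generic.number if r.generic is not None else f"#{r.author_number}"
            )
        else:
            keep.append(r)
    out.residues = keep

    for seg in TM_SEGMENTS:
        n = sum(
            1 for r in out.residues if r.generic is not None and r.generic.segment == seg
        )
        if n < TURN_RESIDUES:
            raise InvariantError(
                f"trimming left {seg} with {n} residues (< {TURN_RESIDUES})"
            )
    return out, removed


def extend_helix(
    model: AnnotatedStructure,
    segment: str,
    donor: AnnotatedStructure,
    direction: str,
    target: AnnotatedSequence,
    warn_rmsd: float = ANCHOR_WARN_RMSD,
) -> tuple[AnnotatedStructure, Optional[GraftSpec]]:
    """Re-model a missing helix end from a donor superposed on the last
    retained helical turn (4 residues, backbone atoms N/CA/C/O).

    Anchor residues keep model coordinates; only donor residues beyond the
    anchor are copied.  A no-op (``None`` graft) when the segment end is
    already complete.
    """
    if direction not in ("N-end", "C-end"):
        raise GraftError(f"direction must be N-end or C-end, got {direction!r}")
    tokens = _segment_tokens(target, segment)
    present = model.generic_positions()
    if direction == "N-end":
        missing = []
        for g in tokens:
            if g in present:
                break
            missing.append(g)
        retained = [g for g in tokens if g in present]
        anchors = retained[:TURN_RESIDUES]
    else:
        missing = []
        for g in reversed(tokens):
            if g in present:
                break
            missing.append(g)
        missing.reverse()
        retained = [g for g in tokens if g in present]
        anchors = retained[-TURN_RESIDUES:]
    if not missing:
        return model, None
    if len(anchors) < TURN_RESIDUES:
        raise GraftError(
            f"{segment} retains fewer than {TURN_RESIDUES} residues to anchor on"
        )

    d_by = donor.by_generic()
    for g in missing:
        if g not in d_by or not d_by[g].has_backbone:
            raise GraftError(f"donor {donor.id} lacks missing position {g}")
    transform, fitted = _superpose_on_anchors(model, donor, anchors)
    warn = fitted > warn_rmsd
    for g in missing:
        _copy_residue_into(
            model, d_by[g], _target_index(target, g), g, transform, warn
        )
    spec = GraftSpec(
        segment=segment,
        donor_structure=donor.id,
        donor_residue_range=(missing[0].number, missing[-1].number),
        anchor_set=tuple((g.number, BACKBONE_ATOMS) for g in anchors),
        kind="helix_extension",
        anchor_rmsd=fitted,
        warning=warn,
    )
    return model, spec


def graft_loop(
    model: AnnotatedStructure,
    segment: str,
    donor: AnnotatedStructure,
    target: AnnotatedSequence,
    warn_rmsd: float = ANCHOR_WARN_RMSD,
) -> tuple[AnnotatedStructure, GraftSpec]:
    """Graft a whole loop from a donor anchored on the adjacent helix ends
    (2 terminal residues of each flanking helix, backbone atoms).

    Conserved loop motifs (the ECL1 three-residue turn, the ICL1
    single-turn helix, the ICL2 two-turn helix) are preserved by virtue of
    the whole-segment copy.
    """
    if segment not in LOOP_FLANKS or segment == "ECL2":
        raise GraftError(f"graft_loop handles ICL1/ECL1/ICL2/ICL3/ECL3, not {segment}")
    prev_helix, next_helix = LOOP_FLANKS[segment]
    present = model.generic_positions()
    prev_tokens = [g for g in _segment_tokens(target, prev_helix) if g in present]
    next_tokens = [g for g in _segment_tokens(target, next_helix) if g in present]
    if len(prev_tokens) < LOOP_ANCHOR_RESIDUES or len(next_tokens) < LOOP_ANCHOR_RESIDUES:
        raise GraftError(
            f"model lacks flanking helix ends ({prev_helix}/{next_helix}) for {segment}"
        )
    anchors = prev_tokens[-LOOP_ANCHOR_RESIDUES:] + next_tokens[:LOOP_ANCHOR_RESIDUES]

    loop_tokens = _segment_tokens(target, segment)
    donor_loop = [
        r
        for r in donor.residues
        if r.generic is not None and r.generic.segment == segment
    ]
    if len(donor_loop) != len(loop_tokens):
        raise GraftError(
            f"donor {donor.id} loop {segment} has {len(donor_loop)} residues, "
            f"target has {len(loop_tokens)}"
        )
    if not all(r.has_backbone for r in donor_loop):
        raise GraftError(f"donor {donor.id} loop {segment} backbone incomplete")

    transform, fitted = _superpose_on_anchors(model, donor, anchors)
    warn = fitted > warn_rmsd
    # clear any partial loop already present
    for r in list(model.residues):
        if r.generic is not None and r.generic.segment == segment:
            model.residues.remove(r)
    for g, donor_res in zip(loop_tokens, donor_loop):
        _copy_residue_into(model, donor_res, _target_index(target, g), g, transform, warn)
    spec = GraftSpec(
        segment=segment,
        donor_structure=donor.id,
        donor_residue_range=(loop_tokens[0].number, loop_tokens[-1].number),
        anchor_set=tuple((g.number, BACKBONE_ATOMS) for g in anchors),
        kind="loop",
        anchor_rmsd=fitted,
        warning=warn,
    )
    return model, spec


_CYS_ECL2 = GenericPosition.from_token("45x50")
_CYS_TM3 = GenericPosition.from_token("3x25")


def graft_ecl2(
    model: AnnotatedStructure,
    donor_first_half: AnnotatedStructure,
    donor_second_half: AnnotatedStructure,
    cys_inference_donor: Optional[AnnotatedStructure],
    target: AnnotatedSequence,
    warn_rmsd: float = ANCHOR_WARN_RMSD,
) -> tuple[AnnotatedStructure, list[GraftSpec]]:
    """Graft ECL2 in two halves anchored on the conserved 45x50 cysteine.

    When the model lacks the 45x50 backbone it is first inferred from
    ``cys_inference_donor`` superposed on the last TM4 residue, the first
    TM5 residue and the conserved TM3 cysteine (3x25).
    """
    present = model.generic_positions()
    tm4 = [g for g in _segment_tokens(target, "TM4") if g in present]
    tm5 = [g for g in _segment_tokens(target, "TM5") if g in present]
    if len(tm4) < LOOP_ANCHOR_RESIDUES or len(tm5) < LOOP_ANCHOR_RESIDUES:
        raise GraftError("model lacks TM4 end / TM5 start to anchor ECL2")

    specs: list[GraftSpec] = []
    ecl2 = _segment_tokens(target, "ECL2")
    if _CYS_ECL2 not in ecl2:
        raise GraftError("target has no 45x50 position annotated in ECL2")
    cys_i = ecl2.index(_CYS_ECL2)
    first_half = ecl2[:cys_i]
    second_half = ecl2[cys_i + 1 :]

    if _CYS_ECL2 not in model.generic_positions(backbone_only=True):
        if cys_inference_donor is None:
            raise GraftError(
                "model lacks the 45x50 backbone and no inference donor was given"
            )
        inf_anchors = [tm4[-1], tm5[0], _CYS_TM3]
        transform, fitted = _superpose_on_anchors(model, cys_inference_donor, inf_anchors)
        d_by = cys_inference_donor.by_generic()
        if _CYS_ECL2 not in d_by:
            raise GraftError(
                f"inference donor {cys_inference_donor.id} lacks 45x50"
            )
        warn = fitted > warn_rmsd
        _copy_residue_into(
            model,
            d_by[_CYS_ECL2],
            _target_index(target, _CYS_ECL2),
            _CYS_ECL2,
            transform,
            warn,
        )
        specs.append(
            GraftSpec(
                segment="ECL2",
                donor_structure=cys_inference_donor.id,
                donor_residue_range=("45x50", "45x50"),
                anchor_set=tuple((g.number, BACKBONE_ATOMS) for g in inf_anchors),
                kind="ecl2_half",
                anchor_rmsd=fitted,
                warning=warn,
            )
        )

    halves = (
        (first_half, donor_first_half, tm4[-LOOP_ANCHOR_RESIDUES:] + [_CYS_ECL2]),
        (second_half, donor_second_half, [_CYS_ECL2] + tm5[:LOOP_ANCHOR_RESIDUES]),
    )
    for tokens, donor, anchors in halves:
        if not tokens:
            continue
        missing = [g for g in tokens if g not in model.generic_positions(backbone_only=True)]
        if not missing:
            continue
        d_by = donor.by_generic()
        for g in tokens:
            if g not in d_by or not d_by[g].has_backbone:
                raise GraftError(f"donor {donor.id} lacks ECL2 position {g}")
        transform, fitted = _superpose_on_anchors(model, donor, anchors)
        warn = fitted > warn_rmsd
        for g in tokens:
            _copy_residue_into(
                model, d_by[g], _target_index(target, g), g, transform, warn
            )
        specs.append(
            GraftSpec(
                segment="ECL2",
                donor_structure=donor.id,
                donor_residue_range=(tokens[0].number, tokens[-1].number),
                anchor_set=tuple((g.number, BACKBONE_ATOMS) for g in anchors),
                kind="ecl2_half",
                anchor_rmsd=fitted,
                warning=warn,
            )
        )
    return model, specs


def swap_bulge_constriction(
    model: AnnotatedStructure,
    window: tuple[str, str, str],
    donor: AnnotatedStructure,
    target_has_bulge: bool,
    target: AnnotatedSequence,
    warn_rmsd: float = ANCHOR_WARN_RMSD,
) -> tuple[AnnotatedStructure, GraftSpec]:
    """Replace a helix window with a donor window matching the target's
    bulge/constriction configuration, anchored on 2 residues either side.
    """
    segment, first, last = window
    if segment not in TM_SEGMENTS:
        raise SwapError(f"swap window must lie inside one TM helix, got {segment}")
    lo = GenericPosition.from_token(first).ordinal
    hi = GenericPosition.from_token(last).ordinal
    seg_tokens = _segment_tokens(target, segment)
    window_tokens = [g for g in seg_tokens if lo <= g.ordinal <= hi]
    if not window_tokens:
        raise SwapError(f"window {first}-{last} covers no target residue")
    has_bulge = any(g.is_bulge for g in window_tokens)
    if has_bulge != target_has_bulge:
        raise SwapError(
            f"target window {first}-{last} bulge={has_bulge}, caller stated "
            f"{target_has_bulge}"
        )
    donor_window = [
        r
        for r in donor.residues
        if r.generic is not None
        and r.generic.segment == segment
        and lo <= r.generic.ordinal <= hi
    ]
    donor_tokens = {r.generic for r in donor_window}
    if donor_tokens != set(window_tokens):
        raise SwapError(
            f"donor {donor.id} window configuration does not match the target "
            f"({sorted(g.number for g in donor_tokens)} vs "
            f"{sorted(g.number for g in window_tokens)})"
        )

    before = [g for g in seg_tokens if g.ordinal < lo][-2:]
    after = [g for g in seg_tokens if g.ordinal > hi][:2]
    if len(before) < 2 or len(after) < 2:
        raise SwapError("window needs 2 flanking residues on each side")
    anchors = before + after
    transform, fitted = _superpose_on_anchors(model, donor, anchors)
    warn = fitted > warn_rmsd
    # remove the model's window residues (including any token the target
    # lacks, e.g. a main-template bulge), then copy the donor window
    for r in list(model.residues):
        if (
            r.generic is not None
            and r.generic.segment == segment
            and lo <= r.generic.ordinal <= hi
        ):
            model.residues.remove(r)
    d_by = donor.by_generic()
    for g in window_tokens:
        _copy_residue_into(model, d_by[g], _target_index(target, g), g, transform, warn)
    spec = GraftSpec(
        segment=segment,
        donor_structure=donor.id,
        donor_residue_range=(window_tokens[0].number, window_tokens[-1].number),
        anchor_set=tuple((g.number, BACKBONE_ATOMS) for g in anchors),
        kind="bulge_swap" if target_has_bulge else "constriction_swap",
        anchor_rmsd=fitted,
        warning=warn,
    )
    return model, spec


def _rotate_about_axis(
    points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle: float
) -> np.ndarray:
    u = axis / np.linalg.norm(axis)
    p = points - origin
    cos, sin = np.cos(angle), np.sin(angle)
    return (
        origin
        + p * cos
        + np.cross(u, p) * sin
        + np.outer(p @ u, u) * (1 - cos)
    )


def add_disulphides(
    model: AnnotatedStructure,
    target: AnnotatedSequence,
    extra_pairs: Sequence[tuple[str, str]] = (),
) -> tuple[AnnotatedStructure, list[tuple[str, str, float]], list[str]]:
    """Close disulphide bridges by rotating cysteine sidechains.

    The cross-class 3x25-45x50 bridge is always attempted; additional pairs
    (e.g. the class-A ECL3 bridge) come in through ``extra_pairs``.  Each
    cysteine's sidechain is rotated about its CA-CB axis in 5° steps to the
    pair of angles minimising the SG-SG distance error; a bridge is
    recorded when the distance lands in [1.9, 2.2] Å.  Non-cysteine or
    absent positions produce a warning, never an error: the target may
    simply lack the bridge.
    """
    bridges: list[tuple[str, str, float]] = []
    warnings: list[str] = []
    pairs = [("3x25", "45x50")] + [tuple(p) for p in extra_pairs]
    t_by_gen = target.by_generic()
    m_by_gen = model.by_generic()

    for tok_a, tok_b in pairs:
        ga = GenericPosition.from_token(tok_a)
        gb = GenericPosition.from_token(tok_b)
        skip = False
        for tok, g in ((tok_a, ga), (tok_b, gb)):
            t_res = t_by_gen.get(g)
            if t_res is None or t_res.amino_acid != "C":
                warnings.append(
                    f"no disulphide {tok_a}-{tok_b}: target residue at {tok} is "
                    f"{'absent' if t_res is None else t_res.amino_acid}, not cysteine"
                )
                skip = True
            elif g not in m_by_gen or not all(
                a in m_by_gen[g].atoms for a in ("CA", "CB", "SG")
            ):
                warnings.append(
                    f"no disulphide {tok_a}-{tok_b}: model residue at {tok} lacks "
                    "CA/CB/SG atoms"
                )
                skip = True
        if skip:
            continue

        ra, rb = m_by_gen[ga], m_by_gen[gb]
        angles = np.deg2rad(np.arange(0.0, 360.0, SS_SCAN_STEP_DEG))
        sg_a = np.array(
            [
                _rotate_about_axis(
                    ra.atoms["SG"][None, :], ra.atoms["CB"],
                    ra.atoms["CB"] - ra.atoms["CA"], ang,
                )[0]
                for ang in angles
            ]
        )
        sg_b = np.array(
            [
                _rotate_about_axis(
                    rb.atoms["SG"][None, :], rb.atoms["CB"],
                    rb.atoms["CB"] - rb.atoms["CA"], ang,
                )[0]
                for ang in angles
            ]
        )
        dists = np.linalg.norm(sg_a[:, None, :] - sg_b[None, :, :], axis=2)
        i, j = np.unravel_index(np.argmin(np.abs(dists - SS_TARGET)), dists.shape)
        best = float(dists[i, j])
        if SS_RANGE[0] <= best <= SS_RANGE[1]:
            ra.atoms["SG"] = sg_a[i]
            rb.atoms["SG"] = sg_b[j]
            model.disulphides.append((ga, gb))
            bridges.append((tok_a, tok_b, best))
        else:
            warnings.append(
                f"disulphide {tok_a}-{tok_b} not closable: best SG-SG {best:.2f} Å"
            )
    return model, bridges, warnings


# --- orchestration ----------------------------------------------------------


def _init_chimera_from_main(
    main: AnnotatedStructure,
    target: AnnotatedSequence,
    provenance: ProvenanceMap,
) -> AnnotatedStructure:
    """Renumber the trimmed main template into target indexing."""
    chimera = AnnotatedStructure(
        id=f"{target.receptor}_chimera", receptor=target.receptor
    )
    t_by_gen = target.by_generic()
    for r in main.residues:
        if r.generic is None or r.generic not in t_by_gen:
            continue
        idx = t_by_gen[r.generic].index
        rec = r.copy()
        rec.chain = "A"
        rec.author_number = idx
        chimera.residues.append(rec)
        provenance.set_backbone(idx, main.id, r.amino_acid)
    chimera.sort_residues()
    chimera.validate()
    return chimera


def _pick_covering_donor(
    catalog: Sequence[CatalogEntry],
    target: AnnotatedSequence,
    needed: Sequence[GenericPosition],
    similarity_cache: dict[str, float],
    exclude: Sequence[str] = (),
) -> Optional[AnnotatedStructure]:
    """Best donor with complete backbone at all ``needed`` positions,
    ordered by similarity, coverage, resolution, id."""
    best = None
    best_key = None
    for structure, annotation in catalog:
        if annotation.structure_id in exclude:
            continue
        d_ok = structure.generic_positions(backbone_only=True)
        if any(g not in d_ok for g in needed):
            continue
        sim = _similarity(target, structure, similarity_cache)
        if sim is None:
            continue
        key = (
            -round(sim * 10),
            -structure_coverage(structure),
            annotation.resolution,
            annotation.structure_id,
        )
        if best_key is None or key < best_key:
            best, best_key = structure, key
    return best


def _similarity(
    target: AnnotatedSequence,
    structure: AnnotatedStructure,
    cache: dict[str, float],
) -> Optional[float]:
    if structure.id not in cache:
        try:
            cache[structure.id] = align_by_generic(target, structure).similarity_pct
        except AlignmentError:
            cache[structure.id] = None
    return cache[structure.id]


def _find_bulge_windows(
    target: AnnotatedSequence, main: AnnotatedStructure
) -> list[tuple[tuple[str, str, str], bool]]:
    """Windows where target and main disagree on a TM bulge token."""
    t_tokens = {
        r.generic for r in target.residues if r.generic is not None
    }
    m_tokens = {r.generic for r in main.residues if r.generic is not None}
    windows = []
    seen_parents = set()
    for g in sorted(
        (t_tokens | m_tokens), key=lambda g: (g.segment, g.ordinal)
    ):
        if not g.is_bulge or g.segment not in TM_SEGMENTS:
            continue
        if (g in t_tokens) == (g in m_tokens):
            continue
        parent = int(g.number.split("x")[1][:2])
        key = (g.segment, parent)
        if key in seen_parents:
            continue
        seen_parents.add(key)
        code = g.number.split("x")[0]
        first = f"{code}x{parent - 1}"
        last = f"{code}x{parent + 2}"
        windows.append(((g.segment, first, last), g in t_tokens))
    return windows


def build_chimera(
    target: AnnotatedSequence,
    catalog: Sequence[CatalogEntry],
    desired_state: str = "inactive",
    options: BuildOptions = BuildOptions(),
) -> tuple[AnnotatedStructure, ProvenanceMap, BuildReport]:
    """Assemble the chimeric template for ``target`` from a catalog.

    Orchestrates: main-template ranking, trimming, helix-end extension,
    loop grafting (ECL2 in halves), bulge/constriction swaps, rotamer
    application with construct-mutation reversion, and disulphide
    construction.  Any stage failure downgrades its segment to unmodeled;
    the build always returns a (possibly partial) chimera with complete
    provenance.
    """
    report = BuildReport(target=target.receptor, desired_state=desired_state)
    provenance = ProvenanceMap()
    sim_cache: dict[str, float] = {}

    scores = rank_main_templates(target, catalog, desired_state)
    report.ranked_templates = [s.structure_id for s in scores]
    by_id = {ann.structure_id: (st, ann) for st, ann in catalog}
    main_structure, main_annotation = by_id[scores[0].structure_id]
    report.main_template = main_structure.id

    trimmed, removed = trim_nonnative(main_structure, main_annotation, target)
    report.trimmed_residues = removed
    chimera = _init_chimera_from_main(trimmed, target, provenance)
    for seg in HELIX_SEGMENTS + ("ECL2",):
        report.segment_sources.setdefault(seg, main_structure.id)

    def note_graft(spec: GraftSpec) -> None:
        report.grafts.append(spec)
        lo = GenericPosition.from_token(spec.donor_residue_range[0]).ordinal
        hi = GenericPosition.from_token(spec.donor_residue_range[1]).ordinal
        for r in chimera.residues:
            if (
                r.generic is not None
                and r.generic.segment == spec.segment
                and lo <= r.generic.ordinal <= hi
            ):
                provenance.set_backbone(
                    r.author_number, spec.donor_structure, r.amino_acid
                )

    # -- helix ends ----------------------------------------------------------
    for seg in HELIX_SEGMENTS:
        for direction in ("N-end", "C-end"):
            tokens = _segment_tokens(target, seg)
            if not tokens:
                continue
            present = chimera.generic_positions()
            run = []
            it = tokens if direction == "N-end" else list(reversed(tokens))
            for g in it:
                if g in present:
                    break
                run.append(g)
            if not run:
                continue
            retained = [g for g in tokens if g in present]
            anchors = (
                retained[:TURN_RESIDUES]
                if direction == "N-end"
                else retained[-TURN_RESIDUES:]
            )
            donor = _pick_covering_donor(
                catalog, target, list(run) + anchors, sim_cache,
                exclude=[main_structure.id],
            )
            if donor is None:
                report.warnings.append(
                    f"no donor covers {seg} {direction}; left unmodeled"
                )
                continue
            try:
                _, spec = extend_helix(
                    chimera, seg, donor, direction, target, options.anchor_warning_rmsd
                )
            except GraftError as exc:
                report.warnings.append(f"{seg} {direction} graft failed: {exc}")
                continue
            if spec is not None:
                note_graft(spec)
                report.segment_sources[f"{seg} {direction}"] = donor.id

    # -- simple loops ----------------------------------------------------------
    for seg in ("ICL1", "ECL1", "ICL2", "ICL3", "ECL3"):
        tokens = _segment_tokens(target, seg)
        if not tokens:
            continue
        present = chimera.generic_positions(backbone_only=True)
        if all(g in present for g in tokens):
            report.segment_sources.setdefault(seg, main_structure.id)
            continue
        choice = select_segment_template(
            seg,
            len(tokens),
            catalog,
            target,
            require_exact_length=options.strict_loop_length,
            exclude_ids=[main_structure.id],
        )
        if choice is None:
            report.segment_sources[seg] = "unmodeled"
            report.warnings.append(f"no loop template for {seg}; left unmodeled")
            continue
        donor = by_id[choice.structure_id][0]
        try:
            _, spec = graft_loop(
                chimera, seg, donor, target, options.anchor_warning_rmsd
            )
        except GraftError as exc:
            report.segment_sources[seg] = "unmodeled"
            report.warnings.append(f"{seg} graft failed: {exc}")
            continue
        note_graft(spec)
        report.segment_sources[seg] = donor.id

    # -- ECL2 ------------------------------------------------------------------
    ecl2_tokens = _segment_tokens(target, "ECL2")
    if ecl2_tokens:
        present = chimera.generic_positions(backbone_only=True)
        if not all(g in present for g in ecl2_tokens):
            cys_i = (
                ecl2_tokens.index(_CYS_ECL2) if _CYS_ECL2 in ecl2_tokens else None
            )
            try:
                if cys_i is None:
                    raise GraftError("target ECL2 lacks a 45x50 annotation")
                first_half = ecl2_tokens[:cys_i]
                second_half = ecl2_tokens[cys_i + 1 :]
                tm4 = [g for g in _segment_tokens(target, "TM4") if g in present]
                tm5 = [g for g in _segment_tokens(target, "TM5") if g in present]
                if len(tm4) < 2 or len(tm5) < 2:
                    raise GraftError("TM4/TM5 anchors unavailable for ECL2")
                need_cys = _CYS_ECL2 not in present
                cys_donor = None
                if need_cys:
                    cys_donor = _pick_covering_donor(
                        catalog, target,
                        [_CYS_ECL2, tm4[-1], tm5[0], _CYS_TM3],
                        sim_cache, exclude=[main_structure.id],
                    )
                    if cys_donor is None:
                        raise GraftError("no donor to infer the 45x50 backbone from")
                donor_first = _pick_covering_donor(
                    catalog, target,
                    list(first_half) + [_CYS_ECL2] + tm4[-2:],
                    sim_cache, exclude=[main_structure.id],
                )
                donor_second = _pick_covering_donor(
                    catalog, target,
                    list(second_half) + [_CYS_ECL2] + tm5[:2],
                    sim_cache, exclude=[main_structure.id],
                )
                if donor_first is None or donor_second is None:
                    raise GraftError("no donor covers an ECL2 half")
                _, specs = graft_ecl2(
                    chimera, donor_first, donor_second, cys_donor, target,
                    options.anchor_warning_rmsd,
                )
                for spec in specs:
                    note_graft(spec)
                report.segment_sources["ECL2"] = "+".join(
                    dict.fromkeys(s.donor_structure for s in specs)
                )
            except GraftError as exc:
                report.segment_sources["ECL2"] = "unmodeled"
                report.warnings.append(f"ECL2 graft failed: {exc}")

    # -- bulge / constriction windows ------------------------------------------
    for window, target_has_bulge in _find_bulge_windows(target, main_structure):
        seg, first, last = window
        lo = GenericPosition.from_token(first).ordinal
        hi = GenericPosition.from_token(last).ordinal
        window_tokens = [
            g for g in _segment_tokens(target, seg) if lo <= g.ordinal <= hi
        ]
        donor = None
        for structure, annotation in catalog:
            if annotation.structure_id == main_structure.id:
                continue
            d_tokens = {
                r.generic
                for r in structure.residues
                if r.generic is not None
                and r.generic.segment == seg
                and lo <= r.generic.ordinal <= hi
                and r.has_backbone
            }
            if d_tokens == set(window_tokens):
                ok = structure.generic_positions(backbone_only=True)
                anchors_ok = True
                seg_tokens = _segment_tokens(target, seg)
                for g in [x for x in seg_tokens if x.ordinal < lo][-2:] + [
                    x for x in seg_tokens if x.ordinal > hi
                ][:2]:
                    if g not in ok:
                        anchors_ok = False
                if anchors_ok:
                    donor = structure
                    break
        if donor is None:
            report.warnings.append(
                f"no swap-in donor with the target's configuration for {seg} "
                f"{first}-{last}"
            )
            continue
        try:
            _, spec = swap_bulge_constriction(
                chimera, window, donor, target_has_bulge, target,
                options.anchor_warning_rmsd,
            )
        except SwapError as exc:
            report.warnings.append(f"bulge swap failed for {seg}: {exc}")
            continue
        note_graft(spec)
        report.segment_sources[f"{seg} {first}-{last}"] = donor.id

    # -- rotamers ---------------------------------------------------------------
    library = build_library([st for st, _ in catalog])
    ranking = report.ranked_templates
    if options.revert_mutations:
        _, reversion_log = revert_construct_mutations(
            chimera, main_annotation, library, ranking
        )
        report.mutation_reversions = reversion_log
        for tok, donor_id in reversion_log:
            g = GenericPosition.from_token(tok)
            res = chimera.by_generic().get(g)
            if res is not None and donor_id is not None:
                provenance.set_sidechain(res.author_number, donor_id)

    raw_pct, _ = chimeric_identity(target, chimera, provenance.original_aa_map())
    if options.apply_rotamers:
        t_by_gen = target.by_generic()
        for r in list(chimera.residues):
            if r.generic is None or r.generic not in t_by_gen:
                continue
            want = t_by_gen[r.generic].amino_acid
            if r.amino_acid == want:
                continue
            if want == "G":
                # glycine has no sidechain: strip and re-type directly
                r.atoms = {k: v for k, v in r.atoms.items() if k in BACKBONE_ATOMS}
                r.amino_acid = "G"
                provenance.set_sidechain(r.author_number, "target-placeholder")
                report.rotamers_applied += 1
                continue
            donor_id = apply_rotamer(chimera, r.generic, want, library, ranking)
            if donor_id is None:
                report.rotamer_fallbacks.append(r.generic.number)
                provenance.set_sidechain(r.author_number, "target-placeholder")
            else:
                report.rotamers_applied += 1
                provenance.set_sidechain(r.author_number, donor_id)
    _, chim_pct = chimeric_identity(target, chimera, provenance.original_aa_map())
    report.raw_identity_pct = raw_pct
    report.chimeric_identity_pct = chim_pct

    # -- disulphides ------------------------------------------------------------
    _, bridges, ss_warnings = add_disulphides(
        chimera, target, options.extra_disulphide_pairs
    )
    report.disulphides = bridges
    report.warnings.extend(ss_warnings)

    # -- bookkeeping ------------------------------------------------------------
    chimera.segment_borders = _chimera_borders(chimera, target)
    chimera.sort_residues()
    chimera.validate()

    modeled = {r.author_number for r in chimera.residues}
    stretch: list[int] = []
    for r in target.residues:
        if r.index not in modeled:
            stretch.append(r.index)
        elif stretch:
            report.unmodeled_stretches.append(
                (_stretch_segment(target, stretch), stretch[0], stretch[-1])
            )
            stretch = []
    if stretch:
        report.unmodeled_stretches.append(
            (_stretch_segment(target, stretch), stretch[0], stretch[-1])
        )

    report.clashes = len(detect_clashes(chimera))
    return chimera, provenance, report


def _stretch_segment(target: AnnotatedSequence, indices: list[int]) -> str:
    segs = list(dict.fromkeys(target.residues[i - 1].segment for i in indices))
    return "+".join(segs)


def _chimera_borders(
    chimera: AnnotatedStructure, target: AnnotatedSequence
) -> dict[str, tuple[int, int]]:
    borders: dict[str, tuple[int, int]] = {}
    for r in chimera.residues:
        seg = target.residues[r.author_number - 1].segment
        lo, hi = borders.get(seg, (r.author_number, r.author_number))
        borders[seg] = (min(lo, r.author_number), max(hi, r.author_number))
    return borders
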