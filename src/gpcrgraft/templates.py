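"""Main-template ranking and alternative local-template selection.

Main templates are ordered lexicographically on five criteria: (i) receptor
class with a fixed fallback map (B2 falls back to B1, Taste2 to A, all other
classes accept only themselves), (ii) activation-state match, (iii) sequence
similarity to the target, (iv) structure coverage (number of generic
positions with backbone coordinates) and (v) crystallographic resolution.
Similarity is compared at 0.1-percentage-point granularity so float noise
cannot reorder near-ties; exact ties fall back to the structure id.

Alternative local templates for a deficient segment are chosen by length
(exactly as many residues as the target, unless relaxed), similarity,
coverage and resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .alignment import align_by_generic
from .types import (
    AlignmentError,
    AnnotatedSequence,
    AnnotatedStructure,
    SelectionError,
    TemplateAnnotation,
)

#: class fallback map: target class -> acceptable template classes in
#: preference order (rank = index)
CLASS_FALLBACK: dict[str, tuple[str, ...]] = {
    "A": ("A",),
    "B1": ("B1",),
    "B2": ("B2", "B1"),
    "C": ("C",),
    "F": ("F",),
    "T2": ("T2", "A"),
}

CatalogEntry = tuple[AnnotatedStructure, TemplateAnnotation]


@dataclass(frozen=True)
class TemplateScore:
    structure_id: str
    class_rank: int
    state_match: bool
    similarity_pct: float
    coverage: int
    resolution: float

    def sort_key(self) -> tuple:
        # similarity at 0.1-point granularity; resolution ascending;
        # structure_id is the final deterministic tie-break
        return (
            self.class_rank,
            not self.state_match,
            -round(self.similarity_pct * 10),
            -self.coverage,
            self.resolution,
            self.structure_id,
        )


def structure_coverage(structure: AnnotatedStructure) -> int:
    """Number of generic positions with complete backbone coordinates."""
    return len(structure.generic_positions(backbone_only=True))


def score_template(
    target: AnnotatedSequence,
    structure: AnnotatedStructure,
    annotation: TemplateAnnotation,
    desired_state: str,
) -> Optional[TemplateScore]:
    """Score one candidate; ``None`` when its class is not eligible."""
    allowed = CLASS_FALLBACK.get(target.gpcr_class)
    if allowed is None:
        raise SelectionError(f"unknown target class {target.gpcr_class!r}")
    cls = annotation.gpcr_class.value
    if cls not in allowed:
        return None
    try:
        aln = align_by_generic(target, structure)
        similarity = aln.similarity_pct
    except AlignmentError:
        return None
    return TemplateScore(
        structure_id=annotation.structure_id,
        class_rank=allowed.index(cls),
        state_match=annotation.state.value == desired_state,
        similarity_pct=similarity,
        coverage=structure_coverage(structure),
        resolution=annotation.resolution,
    )


def order_scores(scores: Sequence[TemplateScore]) -> list[TemplateScore]:
    """Deterministic total order over candidate scores, best first."""
    return sorted(scores, key=TemplateScore.sort_key)


def rank_main_templates(
    target: AnnotatedSequence,
    catalog: Sequence[CatalogEntry],
    desired_state: str,
) -> list[TemplateScore]:
    """Total order over eligible candidates, best first."""
    if not catalog:
        raise SelectionError("template catalog is empty")
    scores = []
    for structure, annotation in catalog:
        s = score_template(target, structure, annotation, desired_state)
        if s is not None:
            scores.append(s)
    if not scores:
        raise SelectionError(
            f"no template of an eligible class for target class "
            f"{target.gpcr_class!r} (fallbacks: {CLASS_FALLBACK[target.gpcr_class]})"
        )
    if not any(s.state_match for s in scores):
        raise SelectionError(
            f"no eligible template in desired state {desired_state!r}"
        )
    return order_scores(scores)


def segment_is_complete(structure: AnnotatedStructure, segment: str) -> bool:
    residues = structure.segment_residues(segment)
    return bool(residues) and all(r.has_backbone for r in residues)


def select_segment_template(
    segment: str,
    target_length: int,
    candidates: Sequence[CatalogEntry],
    target: AnnotatedSequence,
    require_exact_length: bool = True,
    exclude_ids: Sequence[str] = (),
) -> Optional[TemplateScore]:
    """Best local template for one segment, or ``None`` if none survives.

    Candidates lacking a complete backbone for the segment are excluded;
    with the strict length rule only candidates whose segment has exactly
    ``target_length`` residues remain.  Survivors are ordered by similarity,
    coverage, then resolution; absence is a valid outcome (the segment is
    then left to non-template remainder modeling).
    """
    survivors: list[TemplateScore] = []
    for structure, annotation in candidates:
        if annotation.structure_id in exclude_ids:
            continue
        residues = structure.segment_residues(segment)
        if not residues or not all(r.has_backbone for r in residues):
            continue
        if require_exact_length and len(residues) != target_length:
            continue
        try:
            aln = align_by_generic(target, structure)
        except AlignmentError:
            continue
        survivors.append(
            TemplateScore(
                structure_id=annotation.structure_id,
                class_rank=0,
                state_match=True,
                similarity_pct=aln.similarity_pct,
                coverage=structure_coverage(structure),
                resolution=annotation.resolution,
            )
        )
    if not survivors:
        return None
    survivors.sort(
        key=lambda s: (
            -round(s.similarity_pct * 10),
            -s.coverage,
            s.resolution,
            s.structure_id,
        )
    )
    return survivors[0]
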