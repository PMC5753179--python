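"""Target-template correspondence anchored on generic residue numbers.

Residues sharing a generic position are paired directly.  Un-numbered
stretches caught between two shared anchors are paired outside-in from both
anchors; when the two sides differ in length, the surplus residues of the
longer side are gapped at the centre of the stretch so both anchors stay
intact.  Un-numbered N-/C-terminal tails are left unaligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

from Bio.Align import substitution_matrices

from .types import (
    AlignmentError,
    AnnotatedSequence,
    AnnotatedStructure,
    GenericPosition,
    sort_generic,
)


@dataclass(frozen=True)
class AlignedPair:
    """One alignment column; ``None`` on either side is a gap."""

    target_index: Optional[int]
    target_aa: Optional[str]
    template_author_number: Optional[int]
    template_aa: Optional[str]
    generic: Optional[GenericPosition] = None

    @property
    def is_aligned(self) -> bool:
        return self.target_index is not None and self.template_author_number is not None


@dataclass
class PairwiseAlignment:
    pairs: list[AlignedPair] = field(default_factory=list)
    identity_pct: float = 0.0
    similarity_pct: float = 0.0

    @property
    def aligned_count(self) -> int:
        return sum(1 for p in self.pairs if p.is_aligned)


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


def score_alignment(alignment: PairwiseAlignment, matrix=None) -> tuple[float, float]:
    """Identity and similarity percentages over aligned (non-gap) pairs.

    Similarity counts pairs with a strictly positive substitution score
    (BLOSUM62 by default); identity counts exact matches.  Both are
    percentages of ``aligned_count``.
    """
    if matrix is None:
        matrix = load_matrix()
    aligned = [p for p in alignment.pairs if p.is_aligned]
    if not aligned:
        raise AlignmentError("identity/similarity undefined: no aligned pairs")
    ident = sum(1 for p in aligned if p.target_aa == p.template_aa)
    simil = 0
    for p in aligned:
        a, b = p.target_aa, p.template_aa
        try:
            s = matrix[a, b]
        except (KeyError, IndexError):
            s = -1.0
        if s > 0:
            simil += 1
    n = len(aligned)
    return 100.0 * ident / n, 100.0 * simil / n


def _pair_stretch(
    t_res: list, s_res: list
) -> list[tuple[Optional[object], Optional[object]]]:
    """Outside-in pairing of two un-anchored stretches, center gaps."""
    nt, ns = len(t_res), len(s_res)
    n_pairs = min(nt, ns)
    n_head = (n_pairs + 1) // 2
    n_tail = n_pairs - n_head
    out: list[tuple[Optional[object], Optional[object]]] = []
    for i in range(n_head):
        out.append((t_res[i], s_res[i]))
    # surplus of the longer side, gapped at the stretch centre
    if nt > ns:
        for i in range(n_head, nt - n_tail):
            out.append((t_res[i], None))
    elif ns > nt:
        for i in range(n_head, ns - n_tail):
            out.append((None, s_res[i]))
    for i in range(n_tail, 0, -1):
        out.append((t_res[nt - i], s_res[ns - i]))
    return out


def align_by_generic(
    target: AnnotatedSequence, template: AnnotatedStructure, matrix=None
) -> PairwiseAlignment:
    """Anchor-based pairwise alignment keyed on shared generic positions."""
    t_by_gen = target.by_generic()
    s_by_gen = template.by_generic()
    shared = set(t_by_gen) & set(s_by_gen)
    if not shared:
        raise AlignmentError(
            f"no shared generic positions between {target.receptor} and {template.id}"
        )
    shared_sorted = sort_generic(shared)

    t_list = list(target.residues)
    s_list = list(template.residues)
    t_pos = {id(r): i for i, r in enumerate(t_list)}
    s_pos = {id(r): i for i, r in enumerate(s_list)}

    anchors = [(t_pos[id(t_by_gen[g])], s_pos[id(s_by_gen[g])], g) for g in shared_sorted]
    anchors.sort()

    pairs: list[AlignedPair] = []

    def emit(t_res, s_res, generic=None):
        pairs.append(
            AlignedPair(
                target_index=None if t_res is None else t_res.index,
                target_aa=None if t_res is None else t_res.amino_acid,
                template_author_number=None if s_res is None else s_res.author_number,
                template_aa=None if s_res is None else s_res.amino_acid,
                generic=generic,
            )
        )

    prev_t, prev_s = None, None
    for k, (ti, si, g) in enumerate(anchors):
        if k > 0:
            t_mid = t_list[prev_t + 1 : ti]
            s_mid = s_list[prev_s + 1 : si]
            for t_res, s_res in _pair_stretch(t_mid, s_mid):
                # keep a generic label only when both sides agree on it
                gmid = None
                if (
                    t_res is not None
                    and s_res is not None
                    and t_res.generic is not None
                    and t_res.generic == s_res.generic
                ):
                    gmid = t_res.generic
                emit(t_res, s_res, gmid)
        emit(t_list[ti], s_list[si], g)
        prev_t, prev_s = ti, si

    return _scored(PairwiseAlignment(pairs=pairs), matrix)


def _scored(alignment: PairwiseAlignment, matrix=None) -> PairwiseAlignment:
    alignment.identity_pct, alignment.similarity_pct = score_alignment(alignment, matrix)
    return alignment
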