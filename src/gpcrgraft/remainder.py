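"""Hand-off of untemplated stretches.

Residues not covered by any structural template are exported as inputs for
an external comparative-modeling builder (PIR alignment + template
coordinates), and a naive geometric filler is provided so the pipeline is
runnable end to end without external software.  The filler interpolates a
CA trace between flanking anchors and flags everything it invents as
``low_confidence`` — no unflagged invented coordinates ever appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import write_structure
from .types import (
    AnnotatedSequence,
    AnnotatedStructure,
    InputError,
    InvariantError,
    ResidueRecord,
)

CA_SPACING = 3.8  # Å, target consecutive CA-CA distance of filled traces


@dataclass
class RemainderJob:
    chimera: AnnotatedStructure
    target: AnnotatedSequence
    unmodeled_stretches: list[tuple[str, int, int]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def validate(self) -> None:
        spans = sorted((lo, hi) for _, lo, hi in self.unmodeled_stretches)
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise InvariantError("unmodeled stretches overlap")


def export_builder_inputs(job: RemainderJob) -> tuple[str, str]:
    """PIR alignment (target vs chimeric template) plus template PDB text.

    The template row carries gap characters at unmodeled stretches; both
    alignment rows have equal length.  The contract is format fidelity for
    a standard comparative-modeling run, not execution.
    """
    if not job.chimera.residues:
        raise InputError("chimera is empty; nothing to export")
    job.validate()

    modeled = {r.author_number for r in job.chimera.residues}
    target_seq = job.target.sequence
    template_row = "".join(
        aa if (i + 1) in modeled else "-" for i, aa in enumerate(target_seq)
    )
    first = min(modeled)
    last = max(modeled)

    def wrap(s: str) -> str:
        return "\n".join(s[i : i + 75] for i in range(0, len(s), 75))

    pir = (
        f">P1;{job.target.receptor}\n"
        f"sequence:{job.target.receptor}:1::{len(target_seq)}::::0.00: 0.00\n"
        f"{wrap(target_seq)}*\n"
        f">P1;{job.chimera.id}\n"
        f"structureX:{job.chimera.id}:{first}:A:{last}:A::::\n"
        f"{wrap(template_row)}*\n"
    )
    return pir, write_structure(job.chimera)


def _fill_stretch(
    model: AnnotatedStructure,
    target: AnnotatedSequence,
    lo: int,
    hi: int,
) -> bool:
    """Fill one gap of target indices [lo, hi]; returns False if unanchored."""
    by_author = model.by_author()
    n = hi - lo + 1
    left = by_author.get(lo - 1)
    right = by_author.get(hi + 1)

    if left is not None and right is not None:
        a = left.atoms["CA"]
        b = right.atoms["CA"]
        cas = [a + (b - a) * (j + 1) / (n + 1) for j in range(n)]
    elif left is not None or right is not None:
        # terminal stretch: extend along the local chain direction
        anchor = left if left is not None else right
        sign = 1.0 if left is not None else -1.0
        neighbour = by_author.get(anchor.author_number - int(sign))
        if neighbour is not None and "CA" in neighbour.atoms:
            direction = anchor.atoms["CA"] - neighbour.atoms["CA"]
            nrm = np.linalg.norm(direction)
            direction = direction / nrm if nrm > 1e-6 else np.array([0.0, 0.0, sign])
        else:
            direction = np.array([0.0, 0.0, sign])
        base = anchor.atoms["CA"]
        steps = range(1, n + 1) if left is not None else range(n, 0, -1)
        cas = [base + CA_SPACING * k * direction for k in steps]
    else:
        return False

    for j, idx in enumerate(range(lo, hi + 1)):
        ca = cas[j]
        nxt = cas[j + 1] if j + 1 < len(cas) else (
            right.atoms["CA"] if right is not None else ca + np.array([CA_SPACING, 0, 0])
        )
        prev = cas[j - 1] if j > 0 else (
            left.atoms["CA"] if left is not None else ca - np.array([CA_SPACING, 0, 0])
        )
        d = nxt - prev
        nrm = np.linalg.norm(d)
        t_hat = d / nrm if nrm > 1e-6 else np.array([1.0, 0.0, 0.0])
        rec = ResidueRecord(
            chain="A",
            author_number=idx,
            amino_acid=target.residues[idx - 1].amino_acid,
            generic=target.residues[idx - 1].generic,
            atoms={
                "N": ca - 0.6 * t_hat,
                "CA": ca,
                "C": ca + 0.6 * t_hat,
                "O": ca + 0.6 * t_hat + np.array([0.0, 0.0, 1.0]),
            },
            flags={"low_confidence"},
        )
        model.residues.append(rec)
    model.sort_residues()
    return True


def naive_fill(
    model: AnnotatedStructure,
    target: AnnotatedSequence,
    stretches: Sequence[tuple[str, int, int]],
) -> tuple[AnnotatedStructure, list[tuple[str, int, int]]]:
    """Linear-interpolation CA-trace filler for unmodeled stretches.

    Interior gaps are evenly spaced between the flanking anchor CAs;
    terminal stretches are extended along the last chain direction at
    3.8 Å per residue.  All invented residues are flagged
    ``low_confidence``.  Stretches with no flanking anchor on either side
    are left absent and returned as still-unfilled.
    """
    unfilled: list[tuple[str, int, int]] = []
    for seg, lo, hi in stretches:
        if not _fill_stretch(model, target, lo, hi):
            unfilled.append((seg, lo, hi))
    model.validate()
    return model, unfilled
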