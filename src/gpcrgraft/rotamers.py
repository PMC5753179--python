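"""Position-specific sidechain rotamer library.

Sidechain conformations are harvested per (generic position, amino acid)
from a set of annotated structures and transplanted by superposing the
donor residue's N/CA/C backbone frame onto the acceptor residue's.  The
acceptor backbone is never touched: only sidechain atoms are replaced.
Applying rotamers of the target's amino acids to a chimeric template raises
the fraction of residues backed by an identical, experimentally observed
amino acid; the same machinery reverts engineered construct mutations to
wildtype.

Completeness rule: an entry requires a CB atom and a non-empty sidechain
(glycines are excluded).  Canonical per-amino-acid atom sets are not
enforced, so partially resolved sidechains in real structures would need
upstream filtering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import superpose
from .types import (
    AnnotatedSequence,
    AnnotatedStructure,
    BACKBONE_ATOMS,
    GenericPosition,
    InputError,
)

FRAME_ATOMS = ("N", "CA", "C")  # O varies with psi; excluded from the frame


@dataclass(frozen=True)
class RotamerEntry:
    generic: GenericPosition
    amino_acid: str
    source_structure: str
    backbone_frame: np.ndarray          # (3, 3): N, CA, C
    sidechain_atoms: tuple[tuple[str, tuple[float, float, float]], ...]

    def sidechain_dict(self) -> dict[str, np.ndarray]:
        return {name: np.array(xyz) for name, xyz in self.sidechain_atoms}


@dataclass
class RotamerLibrary:
    entries: dict[tuple[GenericPosition, str], list[RotamerEntry]] = field(
        default_factory=dict
    )
    sources: list[str] = field(default_factory=list)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    def lookup(self, generic: GenericPosition, amino_acid: str) -> list[RotamerEntry]:
        return self.entries.get((generic, amino_acid), [])

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def to_jsonl(self) -> str:
        lines = []
        for entries in self.entries.values():
            for e in entries:
                lines.append(
                    json.dumps(
                        {
                            "generic": e.generic.number,
                            "amino_acid": e.amino_acid,
                            "source_structure": e.source_structure,
                            "backbone_frame": e.backbone_frame.tolist(),
                            "sidechain_atoms": [
                                [name, list(xyz)] for name, xyz in e.sidechain_atoms
                            ],
                        }
                    )
                )
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_jsonl(cls, text: str) -> "RotamerLibrary":
        lib = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            entry = RotamerEntry(
                generic=GenericPosition.from_token(d["generic"]),
                amino_acid=d["amino_acid"],
                source_structure=d["source_structure"],
                backbone_frame=np.array(d["backbone_frame"]),
                sidechain_atoms=tuple(
                    (name, tuple(xyz)) for name, xyz in d["sidechain_atoms"]
                ),
            )
            key = (entry.generic, entry.amino_acid)
            lib.entries.setdefault(key, []).append(entry)
            if entry.source_structure not in lib.sources:
                lib.sources.append(entry.source_structure)
        return lib


def build_library(structures: Sequence[AnnotatedStructure]) -> RotamerLibrary:
    """One entry per (structure, generic position, amino acid).

    Residues without generic numbers, glycines, residues with missing
    backbone frames and incomplete sidechains are skipped (logged in
    ``library.skipped``); an empty library is valid.
    """
    lib = RotamerLibrary()
    for st in structures:
        lib.sources.append(st.id)
        for r in st.residues:
            if r.generic is None or r.amino_acid == "G":
                continue
            if not all(a in r.atoms for a in FRAME_ATOMS):
                lib.skipped.append((st.id, r.generic.number, "incomplete_backbone"))
                continue
            side = r.sidechain_atoms()
            if not side or "CB" not in side:
                lib.skipped.append((st.id, r.generic.number, "incomplete_sidechain"))
                continue
            entry = RotamerEntry(
                generic=r.generic,
                amino_acid=r.amino_acid,
                source_structure=st.id,
                backbone_frame=np.array([r.atoms[a] for a in FRAME_ATOMS]),
                sidechain_atoms=tuple(
                    (name, tuple(float(x) for x in xyz)) for name, xyz in side.items()
                ),
            )
            key = (r.generic, r.amino_acid)
            lib.entries.setdefault(key, []).append(entry)
    return lib


def _choose_entry(
    entries: Sequence[RotamerEntry], source_ranking: Optional[Sequence[str]]
) -> RotamerEntry:
    """Donor choice: highest-ranked source first, then source id."""
    if source_ranking:
        rank = {sid: i for i, sid in enumerate(source_ranking)}
        return min(
            entries, key=lambda e: (rank.get(e.source_structure, len(rank)), e.source_structure)
        )
    return min(entries, key=lambda e: e.source_structure)


def apply_rotamer(
    model: AnnotatedStructure,
    position: GenericPosition,
    amino_acid: str,
    library: RotamerLibrary,
    source_ranking: Optional[Sequence[str]] = None,
) -> Optional[str]:
    """Replace the sidechain at ``position`` with a library rotamer.

    Mutates ``model`` in place: backbone atoms stay bit-identical, the old
    sidechain is removed, the donor sidechain is transformed into the model
    residue's N/CA/C frame, and the residue is re-typed to ``amino_acid``.
    Returns the donor structure id, or ``None`` when the library holds no
    entry (the residue is then left for remainder modeling and flagged).
    """
    residue = model.by_generic().get(position)
    if residue is None:
        raise InputError(f"model has no residue at {position}")
    if not all(a in residue.atoms for a in FRAME_ATOMS):
        raise InputError(f"model residue at {position} lacks an N/CA/C frame")

    entries = library.lookup(position, amino_acid)
    if not entries:
        residue.flags.add("low_confidence")
        return None
    entry = _choose_entry(entries, source_ranking)

    target_frame = np.array([residue.atoms[a] for a in FRAME_ATOMS])
    if np.allclose(entry.backbone_frame, target_frame, atol=1e-12):
        transform = None  # donor frame already coincides; copy verbatim
    else:
        transform, _ = superpose(entry.backbone_frame, target_frame)

    backbone = {k: v for k, v in residue.atoms.items() if k in BACKBONE_ATOMS}
    new_atoms = dict(backbone)
    for name, xyz in entry.sidechain_dict().items():
        new_atoms[name] = xyz if transform is None else transform.apply(xyz)
    residue.atoms = new_atoms
    residue.amino_acid = amino_acid
    return entry.source_structure


def revert_construct_mutations(
    model: AnnotatedStructure,
    annotation,
    library: RotamerLibrary,
    source_ranking: Optional[Sequence[str]] = None,
) -> tuple[AnnotatedStructure, list[tuple[str, Optional[str]]]]:
    """Revert engineered construct mutations to wildtype via the library.

    Returns the model and a log of (generic token, donor id or ``None``);
    unresolvable positions are flagged, never silently skipped.
    """
    log: list[tuple[str, Optional[str]]] = []
    by_gen = model.by_generic()
    for mut in annotation.mutations:
        pos = GenericPosition.from_token(mut.generic)
        residue = by_gen.get(pos)
        if residue is None:
            log.append((mut.generic, None))
            continue
        donor = apply_rotamer(model, pos, mut.wildtype_aa, library, source_ranking)
        if donor is not None:
            residue.flags.discard("engineered_mutation")
        log.append((mut.generic, donor))
    return model, log


def detect_clashes(
    model: AnnotatedStructure, cutoff: float = 2.0
) -> list[tuple[int, int, float]]:
    """Inter-residue heavy-atom pairs closer than ``cutoff`` Å.

    Clashing sidechains are only flagged here; re-modeling is delegated to
    the remainder stage.
    """
    nums, coords = [], []
    for r in model.residues:
        for name, xyz in r.atoms.items():
            nums.append(r.author_number)
            coords.append(xyz)
    coords_arr = np.array(coords)
    nums_arr = np.array(nums)
    clashes = []
    from scipy.spatial import cKDTree

    tree = cKDTree(coords_arr)
    for i, j in tree.query_pairs(cutoff):
        if abs(int(nums_arr[i]) - int(nums_arr[j])) >= 2:
            d = float(np.linalg.norm(coords_arr[i] - coords_arr[j]))
            clashes.append((int(nums_arr[i]), int(nums_arr[j]), d))
    return sorted(set(clashes))


def chimeric_identity(
    target: AnnotatedSequence,
    chimera: AnnotatedStructure,
    original_aa: Optional[dict[int, str]] = None,
) -> tuple[float, float]:
    """Identity of the chimera to the target, before and after rotamers.

    ``original_aa`` maps author numbers to the amino acid each residue
    carried when its backbone was sourced (before any rotamer was applied);
    without it the current amino acids are used for both figures.
    """
    t_by_gen = target.by_generic()
    shared = [r for r in chimera.residues if r.generic in t_by_gen]
    if not shared:
        raise InputError("no shared generic positions between target and chimera")
    n = len(shared)
    chim = sum(1 for r in shared if r.amino_acid == t_by_gen[r.generic].amino_acid)
    if original_aa is None:
        raw = chim
    else:
        raw = sum(
            1
            for r in shared
            if original_aa.get(r.author_number, r.amino_acid)
            == t_by_gen[r.generic].amino_acid
        )
    return 100.0 * raw / n, 100.0 * chim / n
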