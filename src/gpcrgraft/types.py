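"""Core domain types for 7TM receptor modeling.

The universal coordinate-bearing object is :class:`AnnotatedStructure`, an
ordered list of residues each of which may carry a *generic position* — a
class-wide structure-based residue number (e.g. ``3x50`` for the reference
position of TM3, ``45x50`` for the conserved ECL2 cysteine between TM4 and
TM5).  Generic positions give cross-receptor residue correspondence and are
the anchors every alignment, ranking and grafting operation in this package
is built on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class GpcrGraftError(Exception):
    """Base class for all package errors."""


class InputError(GpcrGraftError):
    pass


class FormatError(GpcrGraftError):
    pass


class InvariantError(GpcrGraftError):
    pass


class AlignmentError(GpcrGraftError):
    pass


class SelectionError(GpcrGraftError):
    pass


class GraftError(GpcrGraftError):
    pass


class SwapError(GpcrGraftError):
    pass


class EvaluationError(GpcrGraftError):
    pass


class ConditioningError(GpcrGraftError):
    pass


# --- segment vocabulary -----------------------------------------------------

TM_SEGMENTS = ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7")
LOOP_SEGMENTS = ("ICL1", "ECL1", "ICL2", "ECL2", "ICL3", "ECL3")
HELIX_SEGMENTS = TM_SEGMENTS + ("H8",)
ALL_SEGMENTS = HELIX_SEGMENTS + LOOP_SEGMENTS + ("N-term", "C-term")

#: segment -> generic-number segment code (helices one digit, loops two)
SEGMENT_CODES: dict[str, str] = {
    "TM1": "1", "TM2": "2", "TM3": "3", "TM4": "4", "TM5": "5",
    "TM6": "6", "TM7": "7", "H8": "8",
    "ICL1": "12", "ECL1": "23", "ICL2": "34", "ECL2": "45",
    "ICL3": "56", "ECL3": "67",
}
CODE_SEGMENTS = {code: seg for seg, code in SEGMENT_CODES.items()}

#: residue order of the canonical 7TM topology (N-term extracellular)
TOPOLOGY_ORDER = (
    "N-term", "TM1", "ICL1", "TM2", "ECL1", "TM3", "ICL2", "TM4",
    "ECL2", "TM5", "ICL3", "TM6", "ECL3", "TM7", "H8", "C-term",
)

#: flanking helices of each loop, in topology order
LOOP_FLANKS: dict[str, tuple[str, str]] = {
    "ICL1": ("TM1", "TM2"),
    "ECL1": ("TM2", "TM3"),
    "ICL2": ("TM3", "TM4"),
    "ECL2": ("TM4", "TM5"),
    "ICL3": ("TM5", "TM6"),
    "ECL3": ("TM6", "TM7"),
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_TOKEN_RE = re.compile(r"^(\d{1,2})x(\d{2,3})$")


@dataclass(frozen=True, order=True)
class GenericPosition:
    """A structure-based generic residue number such as ``3x50``.

    ``segment`` is the topology label (TM1..TM7, H8, or a loop); ``number``
    is the textual token of the numbering scheme.  A 3-digit suffix (e.g.
    ``5x461``) marks a bulge insertion after the 2-digit parent position.
    """

    segment: str
    number: str

    def __post_init__(self) -> None:
        if self.segment not in ALL_SEGMENTS:
            raise InvariantError(f"unknown segment label {self.segment!r}")
        m = _TOKEN_RE.match(self.number)
        if m is None:
            raise InvariantError(
                f"generic token {self.number!r} does not match <code>x<2-3 digits>"
            )
        code = m.group(1)
        expected = SEGMENT_CODES.get(self.segment)
        if expected is None or code != expected:
            raise InvariantError(
                f"token {self.number!r} inconsistent with segment {self.segment!r}"
                f" (expected code {expected!r})"
            )

    @classmethod
    def from_token(cls, token: str) -> "GenericPosition":
        """Build a position from its token alone, inferring the segment."""
        m = _TOKEN_RE.match(token)
        if m is None:
            raise InvariantError(f"bad generic token {token!r}")
        seg = CODE_SEGMENTS.get(m.group(1))
        if seg is None:
            raise InvariantError(f"no segment with code {m.group(1)!r}")
        return cls(seg, token)

    @property
    def is_bulge(self) -> bool:
        return len(self.number.split("x")[1]) == 3

    @property
    def ordinal(self) -> float:
        """Sort key within a segment; bulge 5x461 sorts between 46 and 47."""
        suffix = self.number.split("x")[1]
        if len(suffix) == 3:
            return int(suffix[:2]) + int(suffix[2]) / 10.0
        return float(int(suffix))

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.number


RESIDUE_FLAGS = frozenset(
    {"missing_backbone", "distorted", "engineered_mutation", "low_confidence"}
)


@dataclass
class ResidueRecord:
    """One residue: author numbering, amino acid, generic position, atoms."""

    chain: str
    author_number: int
    amino_acid: str
    generic: Optional[GenericPosition] = None
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.chain) != 1:
            raise InvariantError(f"chain must be a single character, got {self.chain!r}")
        if self.amino_acid not in AMINO_ACIDS and self.amino_acid != "X":
            raise InvariantError(f"unknown amino acid {self.amino_acid!r}")
        bad = self.flags - RESIDUE_FLAGS
        if bad:
            raise InvariantError(f"unknown residue flags {sorted(bad)}")
        for name, xyz in list(self.atoms.items()):
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise InvariantError(
                    f"atom {name} of residue {self.author_number} has bad coordinates"
                )
            self.atoms[name] = arr

    @property
    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    def backbone_coords(self, atoms: Sequence[str] = BACKBONE_ATOMS) -> np.ndarray:
        try:
            return np.array([self.atoms[a] for a in atoms])
        except KeyError as exc:
            raise InvariantError(
                f"residue {self.author_number} lacks backbone atom {exc.args[0]}"
            ) from exc

    def sidechain_atoms(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.atoms.items() if k not in BACKBONE_ATOMS}

    def copy(self) -> "ResidueRecord":
        return ResidueRecord(
            chain=self.chain,
            author_number=self.author_number,
            amino_acid=self.amino_acid,
            generic=self.generic,
            atoms={k: v.copy() for k, v in self.atoms.items()},
            flags=set(self.flags),
        )


@dataclass
class AnnotatedStructure:
    """An ordered, annotated set of residues with optional ligand atoms."""

    id: str
    receptor: str
    residues: list[ResidueRecord] = field(default_factory=list)
    segment_borders: dict[str, tuple[int, int]] = field(default_factory=dict)
    ligand_atoms: Optional[list[np.ndarray]] = None
    disulphides: list[tuple[GenericPosition, GenericPosition]] = field(
        default_factory=list
    )

    def validate(self) -> None:
        keys = [(r.chain, r.author_number) for r in self.residues]
        if keys != sorted(keys):
            raise InvariantError("residues not ordered by (chain, author_number)")
        if len(set(keys)) != len(keys):
            raise InvariantError("duplicate (chain, author_number)")
        seen: set[GenericPosition] = set()
        for r in self.residues:
            if r.generic is not None:
                if r.generic in seen:
                    raise InvariantError(f"duplicate generic position {r.generic}")
                seen.add(r.generic)
        by_num = {r.author_number for r in self.residues}
        for seg, (lo, hi) in self.segment_borders.items():
            if not any(lo <= n <= hi for n in by_num):
                raise InvariantError(f"segment border {seg} covers no residue")

    # -- lookups -------------------------------------------------------------

    def by_generic(self) -> dict[GenericPosition, ResidueRecord]:
        return {r.generic: r for r in self.residues if r.generic is not None}

    def by_author(self) -> dict[int, ResidueRecord]:
        return {r.author_number: r for r in self.residues}

    def generic_positions(self, backbone_only: bool = False) -> set[GenericPosition]:
        return {
            r.generic
            for r in self.residues
            if r.generic is not None and (not backbone_only or r.has_backbone)
        }

    def segment_residues(self, segment: str) -> list[ResidueRecord]:
        """Residues of a segment, by generic label or by annotated borders."""
        out = [r for r in self.residues if r.generic is not None and r.generic.segment == segment]
        if out:
            return out
        border = self.segment_borders.get(segment)
        if border is None:
            return []
        lo, hi = border
        return [r for r in self.residues if lo <= r.author_number <= hi]

    def copy(self) -> "AnnotatedStructure":
        return AnnotatedStructure(
            id=self.id,
            receptor=self.receptor,
            residues=[r.copy() for r in self.residues],
            segment_borders=dict(self.segment_borders),
            ligand_atoms=None
            if self.ligand_atoms is None
            else [a.copy() for a in self.ligand_atoms],
            disulphides=list(self.disulphides),
        )

    def sort_residues(self) -> None:
        self.residues.sort(key=lambda r: (r.chain, r.author_number))


# --- template annotation (validated JSON schema) ----------------------------


class GpcrClass(str, Enum):
    A = "A"
    B1 = "B1"
    B2 = "B2"
    C = "C"
    F = "F"
    T2 = "T2"


class ActivationState(str, Enum):
    """Consumed as an annotation (defined from TM5/TM6 displacement upstream)."""

    inactive = "inactive"
    intermediate = "intermediate"
    active = "active"


class MutationEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    generic: str
    construct_aa: str = Field(pattern=r"^[ACDEFGHIKLMNPQRSTVWYX]$")
    wildtype_aa: str = Field(pattern=r"^[ACDEFGHIKLMNPQRSTVWYX]$")

    @field_validator("generic")
    @classmethod
    def _valid_token(cls, v: str) -> str:
        GenericPosition.from_token(v)
        return v


class DistortedRange(BaseModel):
    model_config = ConfigDict(extra="forbid")
    segment: str
    first: str
    last: str

    @model_validator(mode="after")
    def _check(self) -> "DistortedRange":
        if self.segment not in ALL_SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}")
        for tok in (self.first, self.last):
            GenericPosition.from_token(tok)
        return self


class TemplateAnnotation(BaseModel):
    """Metadata enabling template ranking and trimming.

    The activation state is an input annotation, never computed here.
    """

    model_config = ConfigDict(extra="forbid")

    structure_id: str
    receptor: str
    gpcr_class: GpcrClass
    state: ActivationState
    resolution: float = Field(gt=0)
    preferred_chain: str = Field(min_length=1, max_length=1)
    missing_segments: list[str] = Field(default_factory=list)
    distorted_ranges: list[DistortedRange] = Field(default_factory=list)
    mutations: list[MutationEntry] = Field(default_factory=list)

    @field_validator("missing_segments")
    @classmethod
    def _segments_known(cls, v: list[str]) -> list[str]:
        for seg in v:
            if seg not in ALL_SEGMENTS:
                raise ValueError(
                    f"unknown segment {seg!r}; allowed: {', '.join(ALL_SEGMENTS)}"
                )
        return v


# --- target-side sequence ---------------------------------------------------


@dataclass(frozen=True)
class SequenceResidue:
    index: int
    amino_acid: str
    segment: str
    generic: Optional[GenericPosition] = None


@dataclass
class AnnotatedSequence:
    """Target receptor sequence with per-residue segment + generic annotation."""

    receptor: str
    gpcr_class: str
    residues: list[SequenceResidue] = field(default_factory=list)

    def validate(self) -> None:
        for i, r in enumerate(self.residues, start=1):
            if r.index != i:
                raise InvariantError(f"indices not contiguous from 1 at {r.index}")
        gens = [r.generic for r in self.residues if r.generic is not None]
        if len(set(gens)) != len(gens):
            raise InvariantError("duplicate generic positions in sequence")

    def by_generic(self) -> dict[GenericPosition, SequenceResidue]:
        return {r.generic: r for r in self.residues if r.generic is not None}

    def segment_residues(self, segment: str) -> list[SequenceResidue]:
        return [r for r in self.residues if r.segment == segment]

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)


def sort_generic(positions: Iterable[GenericPosition]) -> list[GenericPosition]:
    """Sort generic positions in topology order, bulges between parents."""
    seg_rank = {seg: i for i, seg in enumerate(TOPOLOGY_ORDER)}
    return sorted(positions, key=lambda g: (seg_rank[g.segment], g.ordinal))
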