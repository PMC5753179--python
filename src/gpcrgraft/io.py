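"""Readers and writers: PDB coordinates (via gemmi), FASTA, JSON sidecars.

Conventions
-----------
* Author numbering is 1-based and preserved verbatim; no renumbering on read.
* Only the annotated preferred chain is retained.
* Alternate locations resolve to the highest occupancy (tie: first seen).
* Hydrogens are discarded; the pipeline is heavy-atom only.
* Generic residue numbers travel either as an explicit author-number ->
  token mapping (JSON sidecar) or as ``REMARK 250 GENERIC`` lines emitted
  by :func:`write_structure` and understood by :func:`read_structure`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import gemmi
import numpy as np
from Bio import SeqIO
from io import StringIO
from pydantic import ValidationError

from .types import (
    AnnotatedSequence,
    AnnotatedStructure,
    FormatError,
    GenericPosition,
    InputError,
    InvariantError,
    ResidueRecord,
    SequenceResidue,
    TemplateAnnotation,
)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"

GENERIC_REMARK_PREFIX = "REMARK 250 GENERIC"
FLAG_REMARK_PREFIX = "REMARK 250 FLAG"
SOURCE_REMARK_PREFIX = "REMARK 250 SOURCE"


def _validate_atom_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise FormatError(f"truncated ATOM record at line {lineno}")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            int(line[22:26])
        except ValueError as exc:
            raise FormatError(f"unparseable ATOM record at line {lineno}: {exc}") from exc


def _parse_generic_remarks(pdb_text: str) -> dict[int, GenericPosition]:
    numbering: dict[int, GenericPosition] = {}
    for line in pdb_text.splitlines():
        if line.startswith(GENERIC_REMARK_PREFIX):
            parts = line.split()
            # REMARK 250 GENERIC <author_number> <token>
            numbering[int(parts[3])] = GenericPosition.from_token(parts[4])
    return numbering


def _parse_flag_remarks(pdb_text: str) -> dict[int, set[str]]:
    flags: dict[int, set[str]] = {}
    for line in pdb_text.splitlines():
        if line.startswith(FLAG_REMARK_PREFIX):
            parts = line.split()
            flags.setdefault(int(parts[3]), set()).update(parts[4].split(","))
    return flags


def read_structure(
    pdb_text: str,
    annotation: Optional[TemplateAnnotation] = None,
    numbering: Optional[Mapping[int, GenericPosition]] = None,
    structure_id: Optional[str] = None,
) -> AnnotatedStructure:
    """Parse PDB text into an :class:`AnnotatedStructure`.

    Only the preferred chain (from ``annotation``, default the first chain)
    is retained.  When ``numbering`` is not given, ``REMARK 250 GENERIC``
    lines embedded in the text are used if present.
    """
    _validate_atom_lines(pdb_text)
    if numbering is None:
        numbering = _parse_generic_remarks(pdb_text)
    remark_flags = _parse_flag_remarks(pdb_text)

    st = gemmi.read_pdb_string(pdb_text)
    st.setup_entities()
    if len(st) == 0 or len(st[0]) == 0:
        raise InputError("no chains found in PDB text")
    model = st[0]

    preferred = annotation.preferred_chain if annotation is not None else model[0].name
    chain = None
    for ch in model:
        if ch.name == preferred:
            chain = ch
            break
    if chain is None:
        raise InputError(f"preferred chain {preferred!r} not present")

    residues: list[ResidueRecord] = []
    ligand_atoms: list[np.ndarray] = []
    # hetero ligand atoms are captured from every chain (ligands often sit
    # in their own chain); polymer residues only from the preferred chain
    for ch in model:
        for res in ch:
            if res.het_flag == "H" and res.name not in _THREE_TO_ONE and res.name not in (
                "HOH",
                "WAT",
            ):
                for atom in res:
                    if atom.element.name not in ("H", "D"):
                        ligand_atoms.append(
                            np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                        )
    for res in chain:
        is_het = res.het_flag == "H"
        if is_het and res.name in ("HOH", "WAT"):
            continue
        if is_het and res.name not in _THREE_TO_ONE:
            continue
        # altloc: highest occupancy wins, tie -> first encountered
        best: dict[str, tuple[float, int, np.ndarray]] = {}
        for order, atom in enumerate(res):
            if atom.element.name in ("H", "D"):
                continue
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev[0]:
                best[atom.name] = (atom.occ, order, pos)
        if not best:
            continue
        atoms = {name: pos for name, (occ, order, pos) in best.items()}
        num = res.seqid.num
        aa = _THREE_TO_ONE.get(res.name, "X")
        flags = set(remark_flags.get(num, set()))
        rec = ResidueRecord(
            chain=chain.name,
            author_number=num,
            amino_acid=aa,
            generic=numbering.get(num),
            atoms=atoms,
            flags=flags,
        )
        if not rec.has_backbone:
            rec.flags.add("missing_backbone")
        residues.append(rec)

    if not residues:
        raise InputError(f"preferred chain {preferred!r} contains no ATOM records")

    sid = structure_id or (annotation.structure_id if annotation else st.name or "UNKNOWN")
    out = AnnotatedStructure(
        id=sid,
        receptor=annotation.receptor if annotation else sid,
        residues=sorted(residues, key=lambda r: (r.chain, r.author_number)),
        ligand_atoms=ligand_atoms or None,
    )
    out.validate()
    return out


def write_structure(
    model: AnnotatedStructure,
    provenance: Optional[Mapping[int, str]] = None,
) -> str:
    """Serialise a structure to PDB text with provenance/flag REMARKs.

    The output re-reads through :func:`read_structure` to an equal
    structure (coordinates at PDB precision, 3 decimals).
    """
    if not model.residues:
        raise InvariantError("cannot write an empty structure")
    for r in model.residues:
        if not r.atoms:
            raise InvariantError(
                f"residue {r.author_number} has no atoms; refusing to write"
            )

    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for r in model.residues:
        ch = chains.get(r.chain)
        if ch is None:
            ch = gemmi.Chain(r.chain)
            chains[r.chain] = ch
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(r.amino_acid, "UNK")
        res.seqid = gemmi.SeqId(r.author_number, " ")
        res.het_flag = "A"
        for name, xyz in r.atoms.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.b_iso = 0.0
            element = name[0] if name[0] in ("N", "C", "O", "S") else "C"
            atom.element = gemmi.Element(element)
            res.add_atom(atom)
        ch.add_residue(res)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    if model.ligand_atoms:
        lig_chain = gemmi.Chain("L")
        res = gemmi.Residue()
        res.name = "LIG"
        res.seqid = gemmi.SeqId(1, " ")
        res.het_flag = "H"
        for i, xyz in enumerate(model.ligand_atoms, start=1):
            atom = gemmi.Atom()
            atom.name = f"C{i}"
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.element = gemmi.Element("C")
            res.add_atom(atom)
        lig_chain.add_residue(res)
        st[0].add_chain(lig_chain)

    remarks = [f"REMARK 250 STRUCTURE {model.id} RECEPTOR {model.receptor}"]
    for r in model.residues:
        if r.generic is not None:
            remarks.append(
                f"{GENERIC_REMARK_PREFIX} {r.author_number} {r.generic.number}"
            )
    for r in model.residues:
        if r.flags:
            remarks.append(
                f"{FLAG_REMARK_PREFIX} {r.author_number} {','.join(sorted(r.flags))}"
            )
    if provenance:
        for num in sorted(provenance):
            remarks.append(f"{SOURCE_REMARK_PREFIX} {num} {provenance[num]}")

    body = st.make_pdb_string()
    return "\n".join(remarks) + "\n" + body


def read_annotation(json_text: str) -> TemplateAnnotation:
    """Parse and validate a template annotation record."""
    try:
        data = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"annotation is not valid JSON: {exc}") from exc
    try:
        return TemplateAnnotation.model_validate(data)
    except ValidationError as exc:
        raise InputError(f"invalid template annotation: {exc}") from exc


def write_annotation(annotation: TemplateAnnotation) -> str:
    return annotation.model_dump_json(indent=2)


# --- numbering sidecars -----------------------------------------------------


def read_numbering(json_text: str) -> dict[int, GenericPosition]:
    """Author-number -> generic token map from a JSON object."""
    data = json.loads(json_text)
    return {int(k): GenericPosition.from_token(v) for k, v in data.items()}


def write_numbering(structure: AnnotatedStructure) -> str:
    data = {
        str(r.author_number): r.generic.number
        for r in structure.residues
        if r.generic is not None
    }
    return json.dumps(data, indent=0)


# --- sequences --------------------------------------------------------------


def write_fasta(sequence: AnnotatedSequence) -> str:
    seq = sequence.sequence
    lines = [f">{sequence.receptor}"]
    for i in range(0, len(seq), 60):
        lines.append(seq[i : i + 60])
    return "\n".join(lines) + "\n"


def read_fasta(text: str) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(StringIO(text), "fasta")]


def write_sequence_annotation(sequence: AnnotatedSequence) -> str:
    """Per-residue segment + generic-number sidecar for a target sequence."""
    data = {
        "receptor": sequence.receptor,
        "gpcr_class": sequence.gpcr_class,
        "residues": [
            {
                "index": r.index,
                "amino_acid": r.amino_acid,
                "segment": r.segment,
                "generic": None if r.generic is None else r.generic.number,
            }
            for r in sequence.residues
        ],
    }
    return json.dumps(data, indent=0)


def read_sequence_annotation(json_text: str) -> AnnotatedSequence:
    data = json.loads(json_text)
    residues = [
        SequenceResidue(
            index=r["index"],
            amino_acid=r["amino_acid"],
            segment=r["segment"],
            generic=None
            if r.get("generic") is None
            else GenericPosition.from_token(r["generic"]),
        )
        for r in data["residues"]
    ]
    seq = AnnotatedSequence(
        receptor=data["receptor"], gpcr_class=data["gpcr_class"], residues=residues
    )
    seq.validate()
    return seq


# --- catalog manifests ------------------------------------------------------


def load_catalog(manifest_path: str | Path):
    """Load a template catalog from a JSON manifest.

    The manifest is a list of objects with ``structure_id``, ``coordinates``
    (PDB path), ``annotation`` (JSON path) and optional ``numbering``
    (JSON path); relative paths resolve against the manifest location.
    """
    manifest_path = Path(manifest_path)
    entries = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    catalog = []
    for entry in entries:
        ann = read_annotation((root / entry["annotation"]).read_text())
        numbering = None
        if entry.get("numbering"):
            numbering = read_numbering((root / entry["numbering"]).read_text())
        structure = read_structure(
            (root / entry["coordinates"]).read_text(),
            annotation=ann,
            numbering=numbering,
            structure_id=entry.get("structure_id", ann.structure_id),
        )
        catalog.append((structure, ann))
    return catalog
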