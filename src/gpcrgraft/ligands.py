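"""Bioactivity curation: validity filtering, pChEMBL handling, and
non-redundant aggregation per ligand-receptor-species triad.

Activities are compared on the negative-logarithmic (p) scale: a pChEMBL
value is -log10 of a standardised molar activity (Ki, Kd, IC50 or EC50), so
p = 9 corresponds to 1 nM.  Records failing validity checks (missing
pChEMBL, non-binding/functional assay types, disqualifying data-validity or
activity comments) are dropped with an explicit reason code; survivors are
summarised as min/max/mean per (ligand, target, species) triad, with
nanomolar equivalents derived from the p values (never averaged on the
linear scale).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from io import StringIO
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .types import InputError

ASSAY_TYPES = ("binding", "functional", "other")

#: default disqualifying comment terms, mirroring the upstream database's
#: published data-validity categories; configurable via a JSON/TOML file
DEFAULT_DISQUALIFYING_TERMS: dict[str, tuple[str, ...]] = {
    "validity_comment": (
        "potential missing data",
        "potential transcription error",
        "potential author error",
        "author confirmed error",
        "outside typical range",
        "non standard unit for type",
    ),
    "activity_comment": (
        "inconclusive",
        "inactive",
        "not active",
        "undetermined",
        "indeterminate",
        "unspecified",
    ),
}


@dataclass(frozen=True)
class ActivityRecord:
    ligand_id: str
    target_id: str
    species: str
    assay_type: str
    pchembl: Optional[float] = None
    validity_comment: Optional[str] = None
    activity_comment: Optional[str] = None
    source_ref: str = ""

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_TYPES:
            raise InputError(
                f"assay_type must be one of {ASSAY_TYPES}, got {self.assay_type!r}"
            )
        if self.pchembl is not None and not (0.0 < self.pchembl < 20.0):
            raise InputError(f"pchembl {self.pchembl} outside (0, 20)")


@dataclass(frozen=True)
class AggregatedActivity:
    ligand_id: str
    target_id: str
    species: str
    n_records: int
    p_min: float
    p_max: float
    p_mean: float
    nm_min: float  # corresponds to p_max (highest potency)
    nm_max: float  # corresponds to p_min


@dataclass(frozen=True)
class LigandProperties:
    ligand_id: str
    smiles: str
    molecular_weight: float
    hbd: int
    hba: int
    rotatable_bonds: int
    logp: Optional[float] = None
    vendors: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for name in ("hbd", "hba", "rotatable_bonds"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")


def pchembl_to_nanomolar(p: float) -> float:
    """Convert a p value to nanomolar: p = 9 is 1 nM, p = 6 is 1000 nM."""
    if not (0.0 < p < 20.0):
        raise InputError(f"pchembl {p} outside (0, 20)")
    return 10.0 ** (9.0 - p)


def nanomolar_to_pchembl(nm: float) -> float:
    if nm <= 0:
        raise InputError("nanomolar value must be positive")
    import math

    return 9.0 - math.log10(nm)


def filter_records(
    records: Sequence[ActivityRecord],
    disqualifying_terms: Optional[Mapping[str, Iterable[str]]] = None,
) -> tuple[list[ActivityRecord], list[tuple[ActivityRecord, str]]]:
    """Split records into kept and dropped-with-reason.

    Drop rules: absent pChEMBL ("no_pchembl"), assay type other than
    binding/functional ("assay_type_other"), and comments matching the
    disqualifying term lists ("validity_comment" / "activity_comment").
    Conservation holds: kept + dropped = input.
    """
    terms = disqualifying_terms or DEFAULT_DISQUALIFYING_TERMS
    validity_terms = tuple(t.lower() for t in terms.get("validity_comment", ()))
    activity_terms = tuple(t.lower() for t in terms.get("activity_comment", ()))

    kept: list[ActivityRecord] = []
    dropped: list[tuple[ActivityRecord, str]] = []
    for rec in records:
        if rec.pchembl is None:
            dropped.append((rec, "no_pchembl"))
            continue
        if rec.assay_type == "other":
            dropped.append((rec, "assay_type_other"))
            continue
        vc = (rec.validity_comment or "").lower()
        if vc and any(t in vc for t in validity_terms):
            dropped.append((rec, "validity_comment"))
            continue
        ac = (rec.activity_comment or "").lower()
        if ac and any(t in ac for t in activity_terms):
            dropped.append((rec, "activity_comment"))
            continue
        kept.append(rec)
    assert len(kept) + len(dropped) == len(records)
    return kept, dropped


def aggregate_triads(records: Sequence[ActivityRecord]) -> list[AggregatedActivity]:
    """Min/max/mean per (ligand, target, species) triad.

    Means are arithmetic on the p (log) scale; nanomolar columns are
    derived from the p extremes (note nm_min corresponds to p_max).
    """
    for rec in records:
        if rec.pchembl is None:
            raise InputError("aggregate_triads requires pChEMBL on every record")
    if not records:
        return []
    df = pd.DataFrame(
        {
            "ligand_id": [r.ligand_id for r in records],
            "target_id": [r.target_id for r in records],
            "species": [r.species for r in records],
            "pchembl": [r.pchembl for r in records],
        }
    )
    grouped = (
        df.groupby(["ligand_id", "target_id", "species"], sort=True)["pchembl"]
        .agg(["count", "min", "max", "mean"])
        .reset_index()
    )
    out = []
    for row in grouped.itertuples(index=False):
        out.append(
            AggregatedActivity(
                ligand_id=row.ligand_id,
                target_id=row.target_id,
                species=row.species,
                n_records=int(row.count),
                p_min=float(row.min),
                p_max=float(row.max),
                p_mean=float(row.mean),
                nm_min=pchembl_to_nanomolar(float(row.max)),
                nm_max=pchembl_to_nanomolar(float(row.min)),
            )
        )
    return out


def property_filter(
    ligands: Sequence[LigandProperties],
    ranges: Mapping[str, tuple[Optional[float], Optional[float]]] = (),
    require_vendor: bool = False,
    required_fields: Sequence[str] = (),
) -> list[LigandProperties]:
    """Conjunctive range filtering on chemical properties.

    ``ranges`` maps a field name to (min, max); ``None`` bounds are open.
    Ligands with an absent field fail only when that field is listed in
    ``required_fields``; ``require_vendor`` drops ligands without vendors.
    """
    ranges = dict(ranges)
    out = []
    for lig in ligands:
        ok = True
        if require_vendor and not lig.vendors:
            ok = False
        for name, (lo, hi) in ranges.items():
            value = getattr(lig, name, None)
            if value is None:
                if name in required_fields:
                    ok = False
                    break
                continue
            if lo is not None and value < lo:
                ok = False
                break
            if hi is not None and value > hi:
                ok = False
                break
        if ok:
            out.append(lig)
    return out


# --- CSV / SMILES round-trips ----------------------------------------------

ACTIVITY_CSV_COLUMNS = [
    "ligand_id", "target_id", "species", "assay_type", "pchembl",
    "validity_comment", "activity_comment", "source_ref",
]
AGGREGATE_CSV_COLUMNS = [
    "ligand_id", "target_id", "species", "n_records",
    "p_min", "p_max", "p_mean", "nm_min", "nm_max",
]


def records_to_csv(records: Sequence[ActivityRecord]) -> str:
    df = pd.DataFrame([asdict(r) for r in records], columns=ACTIVITY_CSV_COLUMNS)
    return df.to_csv(index=False)


def records_from_csv(csv_text: str) -> list[ActivityRecord]:
    df = pd.read_csv(StringIO(csv_text), dtype=str)
    missing = [c for c in ("ligand_id", "target_id", "species", "assay_type") if c not in df.columns]
    if missing:
        raise InputError(f"activity CSV lacks required columns: {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            p = getattr(row, "pchembl", None)
            p = None if p is None or pd.isna(p) else float(p)
            out.append(
                ActivityRecord(
                    ligand_id=row.ligand_id,
                    target_id=row.target_id,
                    species=row.species,
                    assay_type=row.assay_type,
                    pchembl=p,
                    validity_comment=_opt(getattr(row, "validity_comment", None)),
                    activity_comment=_opt(getattr(row, "activity_comment", None)),
                    source_ref=_opt(getattr(row, "source_ref", None)) or "",
                )
            )
        except (InputError, ValueError) as exc:
            raise InputError(f"bad activity record at CSV row {i}: {exc}") from exc
    return out


def _opt(v):
    if v is None or (isinstance(v, float) and pd.isna(v)) or (isinstance(v, str) and not v):
        return None
    return None if (isinstance(v, str) and v == "nan") or pd.isna(v) else v


def aggregates_to_csv(aggregates: Sequence[AggregatedActivity]) -> str:
    df = pd.DataFrame([asdict(a) for a in aggregates], columns=AGGREGATE_CSV_COLUMNS)
    return df.to_csv(index=False)


def export_ligands(
    subset: Sequence[LigandProperties],
    activities: Sequence[AggregatedActivity],
) -> tuple[str, str]:
    """SMILES flat file (one ligand per line, with identifier) and the
    aggregated-activity CSV restricted to the subset."""
    smiles_lines = [f"{lig.smiles}\t{lig.ligand_id}" for lig in subset]
    ids = {lig.ligand_id for lig in subset}
    rows = [a for a in activities if a.ligand_id in ids]
    return "\n".join(smiles_lines) + ("\n" if smiles_lines else ""), aggregates_to_csv(rows)


PROPERTY_CSV_COLUMNS = [
    "ligand_id", "smiles", "molecular_weight", "hbd", "hba",
    "rotatable_bonds", "logp", "vendors",
]


def properties_to_csv(ligands: Sequence[LigandProperties]) -> str:
    rows = []
    for lig in ligands:
        d = asdict(lig)
        d["vendors"] = ";".join(f"{v}:{c}" for v, c in lig.vendors)
        rows.append(d)
    return pd.DataFrame(rows, columns=PROPERTY_CSV_COLUMNS).to_csv(index=False)


def properties_from_csv(csv_text: str) -> list[LigandProperties]:
    df = pd.read_csv(StringIO(csv_text))
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            vendors_raw = getattr(row, "vendors", None)
            vendors: tuple = ()
            if isinstance(vendors_raw, str) and vendors_raw:
                vendors = tuple(
                    tuple(part.split(":", 1)) for part in vendors_raw.split(";")
                )
            logp = getattr(row, "logp", None)
            out.append(
                LigandProperties(
                    ligand_id=str(row.ligand_id),
                    smiles=str(row.smiles),
                    molecular_weight=float(row.molecular_weight),
                    hbd=int(row.hbd),
                    hba=int(row.hba),
                    rotatable_bonds=int(row.rotatable_bonds),
                    logp=None if logp is None or pd.isna(logp) else float(logp),
                    vendors=vendors,
                )
            )
        except (InputError, ValueError, TypeError) as exc:
            raise InputError(f"bad ligand property record at CSV row {i}: {exc}") from exc
    return out


def load_disqualifying_terms(text: str) -> dict[str, tuple[str, ...]]:
    """Load a disqualifying-term configuration from JSON text."""
    data = json.loads(text)
    return {k: tuple(v) for k, v in data.items()}
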