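"""Region-wise model-vs-reference RMSD reports.

Protocol: one global superposition on the backbone heavy atoms (N/CA/C/O)
of the common 7TM positions, then per-region RMSD measured without
re-fitting, so local errors in loops or the ligand site are exposed rather
than absorbed into the fit.  When several models are compared, RMSD
calculations are restricted to the generic positions present (with
complete backbone) in all of them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .geometry import rmsd, superpose
from .types import (
    AnnotatedStructure,
    EvaluationError,
    GenericPosition,
    TM_SEGMENTS,
    sort_generic,
)

LIGAND_SITE_RADIUS = 5.0  # Å, CA distance to any reference ligand heavy atom


@dataclass
class RegionRMSDReport:
    model_id: str
    reference_id: str
    superposition_region: str
    regions: dict[str, tuple[int, float]] = field(default_factory=dict)
    common_set_size: int = 0
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model_id,
                "reference": self.reference_id,
                "superposition_region": self.superposition_region,
                "common_set_size": self.common_set_size,
                "regions": {
                    name: {"n_residues": n, "backbone_rmsd": r}
                    for name, (n, r) in self.regions.items()
                },
                "notes": self.notes,
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["region\tn_residues\tbackbone_rmsd"]
        for name, (n, r) in self.regions.items():
            lines.append(f"{name}\t{n}\t{r:.3f}")
        return "\n".join(lines) + "\n"


def common_residues(models: Sequence[AnnotatedStructure]) -> set[GenericPosition]:
    """Generic positions with complete backbone in every input structure."""
    if len(models) < 2:
        raise EvaluationError("common-residue restriction needs >= 2 structures")
    common = models[0].generic_positions(backbone_only=True)
    for m in models[1:]:
        common &= m.generic_positions(backbone_only=True)
    if not common:
        raise EvaluationError("no generic position is present in all structures")
    return common


def _ligand_site_positions(
    reference: AnnotatedStructure, radius: float = LIGAND_SITE_RADIUS
) -> Optional[set[GenericPosition]]:
    if not reference.ligand_atoms:
        return None
    lig = np.array(reference.ligand_atoms)
    site = set()
    for r in reference.residues:
        if r.generic is None or "CA" not in r.atoms:
            continue
        if np.min(np.linalg.norm(lig - r.atoms["CA"], axis=1)) <= radius:
            site.add(r.generic)
    return site


def evaluate_model(
    model: AnnotatedStructure,
    reference: AnnotatedStructure,
    regions: Optional[Mapping[str, set[GenericPosition]]] = None,
    restrict_to: Optional[set[GenericPosition]] = None,
    ligand_site: Optional[set[GenericPosition]] = None,
    refit_regions: bool = False,
) -> RegionRMSDReport:
    """Backbone RMSD per region after one global 7TM fit.

    ``regions`` adds custom position sets to the standard overall / 7TM /
    ECL2 / ligand-site report; ``restrict_to`` intersects everything with
    an externally computed common-residue set.  ``refit_regions`` switches
    to per-region superposition (documented alternative, off by default).
    """
    common = model.generic_positions(backbone_only=True) & reference.generic_positions(
        backbone_only=True
    )
    if restrict_to is not None:
        common &= set(restrict_to)
    if len(common) < 3:
        raise EvaluationError("fewer than 3 common backbone-complete positions")

    m_by = model.by_generic()
    r_by = reference.by_generic()

    def coords(positions: Sequence[GenericPosition]):
        ordered = sort_generic(positions)
        a = np.concatenate([m_by[g].backbone_coords() for g in ordered])
        b = np.concatenate([r_by[g].backbone_coords() for g in ordered])
        return a, b

    tm_positions = [g for g in common if g.segment in TM_SEGMENTS]
    if len(tm_positions) < 3:
        raise EvaluationError("fewer than 3 common 7TM positions to superpose on")
    mob, ref = coords(tm_positions)
    transform, _ = superpose(mob, ref)

    report = RegionRMSDReport(
        model_id=model.id,
        reference_id=reference.id,
        superposition_region="7TM",
        common_set_size=len(common),
    )

    region_sets: dict[str, set[GenericPosition]] = {
        "overall": set(common),
        "7TM": set(tm_positions),
        "ECL2": {g for g in common if g.segment == "ECL2"},
    }
    site = ligand_site if ligand_site is not None else _ligand_site_positions(reference)
    if site is not None:
        region_sets["ligand_site"] = {g for g in site if g in common}
    else:
        report.notes.append("ligand_site omitted: reference has no ligand and no "
                            "explicit position set was given")
    if regions:
        for name, positions in regions.items():
            region_sets[name] = {g for g in positions if g in common}

    for name, positions in region_sets.items():
        if not positions:
            report.notes.append(f"region {name} empty within the common set")
            continue
        a, b = coords(list(positions))
        if refit_regions and len(positions) >= 3:
            t_local, fitted = superpose(a, b)
            report.regions[name] = (len(positions), fitted)
        else:
            report.regions[name] = (len(positions), rmsd(transform.apply(a), b))
    return report
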