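"""Shared fixtures: toy receptors, defect catalogs, and a finished build."""

from __future__ import annotations

import dataclasses

import pytest

from gpcrgraft.assembly import build_chimera
from gpcrgraft.toys import ToySpec, generate_toy_receptor, make_template_catalog

MAIN_DEFECTS = [
    ("truncate", {"segment": "TM1", "n": 4, "end": "N"}),
    ("truncate", {"segment": "TM3", "n": 3, "end": "N"}),
    ("truncate", {"segment": "TM5", "n": 3, "end": "N"}),
    ("truncate", {"segment": "TM5", "n": 4, "end": "C"}),
    ("truncate", {"segment": "TM6", "n": 3, "end": "N"}),
    ("truncate", {"segment": "H8", "n": 3, "end": "C"}),
    ("delete_segment", {"segment": "ECL1"}),
    ("delete_segment", {"segment": "ICL2"}),
    ("delete_segment", {"segment": "ECL2"}),
    ("delete_segment", {"segment": "ECL3"}),
    ("mutate", {"token": "2x50", "new_aa": "W"}),
]


def specialist_donor(name: str, keeps: list[str], n_div: int) -> dict:
    """A donor intact only where it donates; diverged to a distinct receptor."""
    defects: list = [("diverge", {"n": n_div})]
    for seg in ("ICL1", "ECL1", "ICL2", "ECL2", "ICL3", "ECL3"):
        if seg not in keeps:
            defects.append(("delete_segment", {"segment": seg}))
    return {"id": name, "receptor": f"TOYR_{name}", "defects": defects}


def multi_defect_catalog(base: ToySpec):
    """Defective main template + per-segment specialist donors (no intact twin)."""
    variants = [
        {"id": "MAIN01", "defects": MAIN_DEFECTS},
        specialist_donor("DON_HELIX", ["ICL1"], 8),
        specialist_donor("DON_ECL1", ["ECL1"], 12),
        specialist_donor("DON_ICL2", ["ICL2"], 14),
        specialist_donor("DON_ECL2", ["ECL2"], 16),
        specialist_donor("DON_ECL3", ["ECL3"], 18),
    ]
    return make_template_catalog(base, variants)[1:]


@pytest.fixture(scope="session")
def base_spec() -> ToySpec:
    return ToySpec(seed=11)


@pytest.fixture(scope="session")
def intact_toy(base_spec):
    return generate_toy_receptor(base_spec)


@pytest.fixture(scope="session")
def twin_catalog(base_spec):
    """Defective same-receptor main + one diverged intact-twin donor."""
    variants = [
        {
            "id": "MAINTWIN",
            "defects": [
                ("truncate", {"segment": "TM5", "n": 5, "end": "C"}),
                ("delete_segment", {"segment": "ECL1"}),
            ],
        },
        {"id": "DONORTWIN", "receptor": "TOYR_D", "defects": [("diverge", {"n": 6})]},
    ]
    return make_template_catalog(base_spec, variants)[1:]


@pytest.fixture(scope="session")
def scenario_build(base_spec, intact_toy):
    """The multi-defect scenario built once: (truth, target, chimera,
    provenance, report, catalog)."""
    truth, target, _ = intact_toy
    catalog = multi_defect_catalog(base_spec)
    chimera, provenance, report = build_chimera(target, catalog, "inactive")
    return truth, target, chimera, provenance, report, catalog
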