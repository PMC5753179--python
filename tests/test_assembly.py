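"""Grafting contracts: trimming, anchored recovery, swaps, disulphides,
and the full chimera orchestration."""

import dataclasses

import numpy as np
import pytest

from gpcrgraft.assembly import (
    BuildOptions,
    add_disulphides,
    build_chimera,
    extend_helix,
    graft_ecl2,
    graft_loop,
    swap_bulge_constriction,
    trim_nonnative,
    _init_chimera_from_main,
    ProvenanceMap,
)
from gpcrgraft.toys import ToySpec, generate_toy_receptor, make_template_catalog
from gpcrgraft.types import (
    GenericPosition,
    GraftError,
    InvariantError,
    SelectionError,
    SwapError,
)


def target_chimera(structure, target):
    """Renumber a toy structure into target indexing for graft unit tests."""
    return _init_chimera_from_main(structure, target, ProvenanceMap())


def backbone_diff(chimera, truth, tokens):
    t_by, c_by = truth.by_generic(), chimera.by_generic()
    return max(
        float(np.abs(c_by[g].backbone_coords() - t_by[g].backbone_coords()).max())
        for g in tokens
    )


@pytest.fixture(scope="module")
def spec():
    return ToySpec(seed=31)


@pytest.fixture(scope="module")
def toy(spec):
    return generate_toy_receptor(spec)


class TestTrim:
    def test_clean_annotation_unchanged(self, toy):
        structure, seq, ann = toy
        trimmed, removed = trim_nonnative(structure, ann, seq)
        assert removed == []
        assert len(trimmed.residues) == len(structure.residues)

    def test_distorted_range_removed(self, spec, toy):
        _, seq, _ = toy
        defective = dataclasses.replace(
            spec,
            structure_id="DIST",
            defects=(
                ("distort", {"segment": "TM5", "first": "5x54", "last": "5x59"}),
            ),
        )
        structure, _, ann = generate_toy_receptor(defective)
        trimmed, removed = trim_nonnative(structure, ann, seq)
        assert len(removed) == 6
        assert len(trimmed.residues) == len(structure.residues) - 6
        for tok in ("5x54", "5x59"):
            assert GenericPosition.from_token(tok) not in trimmed.by_generic()

    def test_overtrimming_is_integrity_error(self, spec, toy):
        _, seq, _ = toy
        defective = dataclasses.replace(
            spec,
            structure_id="DIST",
            defects=(
                ("distort", {"segment": "TM2", "first": "2x40", "last": "2x56"}),
            ),
        )
        structure, _, ann = generate_toy_receptor(defective)
        with pytest.raises(InvariantError):
            trim_nonnative(structure, ann, seq)


class TestExtendHelix:
    @pytest.mark.parametrize(
        "segment,n,end,direction",
        [
            ("TM1", 4, "N", "N-end"),
            ("TM3", 3, "N", "N-end"),
            ("TM5", 3, "N", "N-end"),
            ("TM5", 5, "C", "C-end"),
            ("TM6", 3, "N", "N-end"),
            ("H8", 3, "C", "C-end"),
        ],
    )
    def test_recovers_deleted_end_exactly(self, spec, toy, segment, n, end, direction):
        truth, seq, _ = toy
        defective = dataclasses.replace(
            spec,
            structure_id="TRUNC",
            defects=(("truncate", {"segment": segment, "n": n, "end": end}),),
        )
        structure, _, _ = generate_toy_receptor(defective)
        model = target_chimera(structure, seq)
        before = {
            r.author_number: {k: v.copy() for k, v in r.atoms.items()}
            for r in model.residues
        }
        _, graft = extend_helix(model, segment, truth, direction, seq)
        assert graft is not None
        assert graft.anchor_rmsd < 1e-9
        lo, hi = graft.donor_residue_range
        restored = [
            g
            for g in (GenericPosition.from_token(lo), GenericPosition.from_token(hi))
        ]
        assert backbone_diff(model, truth, restored) < 0.01
        # anchors (and every pre-existing residue) bit-unchanged
        for r in model.residues:
            if r.author_number in before:
                for name, xyz in before[r.author_number].items():
                    assert np.array_equal(r.atoms[name], xyz)

    def test_complete_segment_is_noop(self, toy):
        truth, seq, _ = toy
        model = target_chimera(truth, seq)
        n_before = len(model.residues)
        _, graft = extend_helix(model, "TM5", truth, "C-end", seq)
        assert graft is None
        assert len(model.residues) == n_before

    def test_donor_missing_anchor_is_error(self, spec, toy):
        truth, seq, _ = toy
        defective = dataclasses.replace(
            spec,
            structure_id="TRUNC",
            defects=(("truncate", {"segment": "TM5", "n": 5, "end": "C"}),),
        )
        structure, _, _ = generate_toy_receptor(defective)
        model = target_chimera(structure, seq)
        bad_donor = structure  # also lacks the missing positions
        with pytest.raises(GraftError):
            extend_helix(model, "TM5", bad_donor, "C-end", seq)


class TestGraftLoop:
    @pytest.mark.parametrize("segment", ["ICL1", "ECL1", "ICL2", "ICL3", "ECL3"])
    def test_recovers_deleted_loop_exactly(self, spec, toy, segment):
        truth, seq, _ = toy
        defective = dataclasses.replace(
            spec,
            structure_id="NOLOOP",
            defects=(("delete_segment", {"segment": segment}),),
        )
        structure, _, _ = generate_toy_receptor(defective)
        model = target_chimera(structure, seq)
        _, graft = graft_loop(model, segment, truth, seq)
        tokens = [r.generic for r in seq.segment_residues(segment)]
        assert backbone_diff(model, truth, tokens) < 0.01
        assert graft.anchor_rmsd < 1e-9

    def test_self_graft_changes_nothing(self, toy):
        truth, seq, _ = toy
        model = target_chimera(truth, seq)
        before = {
            r.author_number: {k: v.copy() for k, v in r.atoms.items()}
            for r in model.residues
        }
        graft_loop(model, "ECL1", model.copy(), seq)
        for r in model.residues:
            for name, xyz in before[r.author_number].items():
                assert np.allclose(r.atoms[name], xyz, atol=1e-6)

    def test_missing_flanking_helix_is_error(self, spec, toy):
        truth, seq, _ = toy
        structure, _, _ = generate_toy_receptor(
            dataclasses.replace(
                spec,
                structure_id="NOLOOP",
                defects=(("delete_segment", {"segment": "ECL1"}),),
            )
        )
        model = target_chimera(structure, seq)
        for r in list(model.residues):
            if r.generic is not None and r.generic.segment == "TM2":
                model.residues.remove(r)
        with pytest.raises(GraftError):
            graft_loop(model, "ECL1", truth, seq)

    def test_length_mismatch_refused(self, spec, toy):
        truth, seq, _ = toy
        short_spec = dataclasses.replace(
            spec,
            structure_id="SHORTLOOP",
            loop_lengths=tuple(
                (seg, n - 1 if seg == "ICL1" else n) for seg, n in spec.loop_lengths
            ),
        )
        donor, _, _ = generate_toy_receptor(short_spec)
        defective, _, _ = generate_toy_receptor(
            dataclasses.replace(
                spec,
                structure_id="NOLOOP",
                defects=(("delete_segment", {"segment": "ICL1"}),),
            )
        )
        model = target_chimera(defective, seq)
        with pytest.raises(GraftError):
            graft_loop(model, "ICL1", donor, seq)


class TestGraftEcl2:
    def test_recovery_with_cys_retained(self, spec, toy):
        truth, seq, _ = toy
        structure, _, _ = generate_toy_receptor(
            dataclasses.replace(
                spec,
                structure_id="NOECL2",
                defects=(("delete_segment", {"segment": "ECL2", "keep": ("45x50",)}),),
            )
        )
        model = target_chimera(structure, seq)
        _, specs = graft_ecl2(model, truth, truth, None, seq)
        assert len(specs) == 2  # two halves, no inference needed
        tokens = [r.generic for r in seq.segment_residues("ECL2")]
        assert backbone_diff(model, truth, tokens) < 0.01

    def test_recovery_with_cys_inferred(self, spec, toy):
        truth, seq, _ = toy
        structure, _, _ = generate_toy_receptor(
            dataclasses.replace(
                spec,
                structure_id="NOECL2",
                defects=(("delete_segment", {"segment": "ECL2"}),),
            )
        )
        model = target_chimera(structure, seq)
        _, specs = graft_ecl2(model, truth, truth, truth, seq)
        assert len(specs) == 3  # inference + two halves
        g = GenericPosition.from_token("45x50")
        assert backbone_diff(model, truth, [g]) < 0.01
        tokens = [r.generic for r in seq.segment_residues("ECL2")]
        assert backbone_diff(model, truth, tokens) < 0.01

    def test_missing_cys_without_donor_is_error(self, spec, toy):
        truth, seq, _ = toy
        structure, _, _ = generate_toy_receptor(
            dataclasses.replace(
                spec,
                structure_id="NOECL2",
                defects=(("delete_segment", {"segment": "ECL2"}),),
            )
        )
        model = target_chimera(structure, seq)
        with pytest.raises(GraftError, match="45x50"):
            graft_ecl2(model, truth, truth, None, seq)

    def test_intact_ecl2_unchanged(self, toy):
        truth, seq, _ = toy
        model = target_chimera(truth, seq)
        before = {
            r.author_number: {k: v.copy() for k, v in r.atoms.items()}
            for r in model.residues
        }
        graft_ecl2(model, truth, truth, truth, seq)
        for r in model.residues:
            for name, xyz in before[r.author_number].items():
                assert np.allclose(r.atoms[name], xyz, atol=1e-6)


class TestBulgeSwap:
    def bulged_spec(self, spec, sid="BULGED"):
        return dataclasses.replace(
            spec,
            structure_id=sid,
            defects=(("bulge", {"segment": "TM5", "after": "5x46"}),),
        )

    def test_insert_bulge_from_donor(self, spec):
        """Target carries a TM5 bulge, the main template does not: the
        swapped-in donor window restores the target's own geometry."""
        truth, seq, _ = generate_toy_receptor(self.bulged_spec(spec))
        plain, _, _ = generate_toy_receptor(
            dataclasses.replace(spec, structure_id="PLAIN")
        )
        model = target_chimera(plain, seq)
        window = ("TM5", "5x45", "5x48")
        _, graft = swap_bulge_constriction(model, window, truth, True, seq)
        tokens = [
            g
            for g in truth.by_generic()
            if g.segment == "TM5" and 45 <= g.ordinal <= 48
        ]
        assert any(g.is_bulge for g in tokens)
        assert backbone_diff(model, truth, tokens) < 0.01
        assert graft.kind == "bulge_swap"
        assert graft.anchor_rmsd < 0.1
        tm5 = [r for r in model.residues if r.generic and r.generic.segment == "TM5"]
        assert len(tm5) == len(seq.segment_residues("TM5"))

    def test_remove_main_template_bulge(self, spec, toy):
        """Main template has a bulge the target lacks: after the swap the
        window length equals the target's."""
        truth, seq, _ = toy
        bulged, _, _ = generate_toy_receptor(self.bulged_spec(spec))
        model = target_chimera(bulged, seq)  # bulge token dropped on renumber
        window = ("TM5", "5x45", "5x48")
        _, graft = swap_bulge_constriction(model, window, truth, False, seq)
        tokens = [
            g for g in seq.by_generic() if g.segment == "TM5" and 45 <= g.ordinal <= 48
        ]
        assert backbone_diff(model, truth, tokens) < 0.01
        tm5 = [r for r in model.residues if r.generic and r.generic.segment == "TM5"]
        assert len(tm5) == len(seq.segment_residues("TM5"))

    def test_mismatching_donor_configuration_rejected(self, spec):
        truth, seq, _ = generate_toy_receptor(self.bulged_spec(spec))
        plain, _, _ = generate_toy_receptor(
            dataclasses.replace(spec, structure_id="PLAIN")
        )
        model = target_chimera(plain, seq)
        window = ("TM5", "5x45", "5x48")
        with pytest.raises(SwapError):
            swap_bulge_constriction(model, window, plain, True, seq)


class TestDisulphides:
    def test_planted_pair_lands_in_band(self, toy):
        truth, seq, _ = toy
        model = target_chimera(truth, seq)
        _, bridges, warnings = add_disulphides(model, seq)
        assert len(bridges) == 1
        a, b, dist = bridges[0]
        assert (a, b) == ("3x25", "45x50")
        assert 1.9 <= dist <= 2.2
        assert model.disulphides

    def test_non_cysteine_target_warns_and_skips(self, spec):
        mut_spec = dataclasses.replace(
            spec,
            structure_id="SER",
            defects=(
                ("mutate", {"token": "3x25", "new_aa": "S", "engineered": False}),
            ),
        )
        structure, seq, _ = generate_toy_receptor(mut_spec)
        model = target_chimera(structure, seq)
        _, bridges, warnings = add_disulphides(model, seq)
        assert bridges == []
        assert any("not cysteine" in w for w in warnings)
        assert not model.disulphides

    def test_exactly_one_bridge_recorded(self, toy):
        truth, seq, _ = toy
        model = target_chimera(truth, seq)
        add_disulphides(model, seq)
        assert len(model.disulphides) == 1


class TestBuildChimera:
    def test_identical_complete_template_trivial_build(self, base_spec, intact_toy):
        _, seq, _ = intact_toy
        catalog = make_template_catalog(base_spec, [])
        chimera, provenance, report = build_chimera(seq, catalog, "inactive")
        assert report.grafts == []
        assert report.raw_identity_pct == pytest.approx(100.0)
        assert report.chimeric_identity_pct == pytest.approx(100.0)
        assert provenance.backbone_sources() == {base_spec.structure_id}

    def test_empty_catalog_is_selection_error(self, intact_toy):
        _, seq, _ = intact_toy
        with pytest.raises(SelectionError):
            build_chimera(seq, [], "inactive")

    def test_multi_defect_scenario_recovers_truth(self, scenario_build):
        truth, target, chimera, provenance, report, _ = scenario_build
        assert len(provenance.backbone_sources()) >= 6
        tokens = [g for g in chimera.by_generic() if g in truth.by_generic()]
        assert backbone_diff(chimera, truth, tokens) < 0.01
        assert report.chimeric_identity_pct >= report.raw_identity_pct
        assert report.disulphides and 1.9 <= report.disulphides[0][2] <= 2.2

    def test_provenance_complete_and_gaps_listed(self, scenario_build):
        _, target, chimera, provenance, report, _ = scenario_build
        modeled = {r.author_number for r in chimera.residues}
        for idx in modeled:
            assert provenance.entries[idx].backbone_source != "unmodeled"
        listed = set()
        for _, lo, hi in report.unmodeled_stretches:
            listed.update(range(lo, hi + 1))
        all_indices = {r.index for r in target.residues}
        assert listed == all_indices - modeled

    def test_stage_failure_degrades_not_aborts(self, base_spec, intact_toy):
        """With no donor covering a deleted loop, the build still succeeds
        and reports the segment as unmodeled."""
        _, seq, _ = intact_toy
        variants = [
            {
                "id": "MAINX",
                "defects": [("delete_segment", {"segment": "ECL3"})],
            }
        ]
        catalog = make_template_catalog(base_spec, variants)[1:]
        chimera, _, report = build_chimera(seq, catalog, "inactive")
        assert any(seg == "ECL3" for seg, *_ in report.unmodeled_stretches)
        assert report.segment_sources["ECL3"] == "unmodeled"
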