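"""Rotamer library build/application: backbone immutability, recovery."""

import dataclasses

import numpy as np
import pytest

from gpcrgraft.rotamers import (
    RotamerLibrary,
    apply_rotamer,
    build_library,
    chimeric_identity,
    revert_construct_mutations,
)
from gpcrgraft.toys import ToySpec, generate_toy_receptor, make_template_catalog
from gpcrgraft.types import GenericPosition


@pytest.fixture(scope="module")
def spec():
    return ToySpec(seed=23)


@pytest.fixture(scope="module")
def toy(spec):
    return generate_toy_receptor(spec)


class TestBuildLibrary:
    def test_empty_input_empty_library(self):
        lib = build_library([])
        assert len(lib) == 0

    def test_three_twins_three_entries_per_position(self, spec, toy):
        structure, _, _ = toy
        twins = [structure, structure.copy(), structure.copy()]
        twins[1].id, twins[2].id = "T2", "T3"
        lib = build_library(twins)
        g = GenericPosition.from_token("3x50")
        aa = structure.by_generic()[g].amino_acid
        assert len(lib.lookup(g, aa)) == 3

    def test_incomplete_sidechains_skipped(self, spec):
        n_drop = 2
        defects = tuple(
            ("drop_sidechain", {"token": t}) for t in ("2x45", "6x55")[:n_drop]
        )
        structure, _, _ = generate_toy_receptor(
            dataclasses.replace(spec, defects=defects)
        )
        intact, _, _ = generate_toy_receptor(spec)
        lib_full = build_library([intact])
        lib_holey = build_library([structure])
        n_gly = sum(
            1 for r in intact.residues if r.generic and r.amino_acid == "G"
        )
        assert len(lib_holey) == len(lib_full) - n_drop
        assert len(lib_holey.skipped) == n_drop

    def test_jsonl_round_trip(self, toy):
        structure, _, _ = toy
        lib = build_library([structure])
        again = RotamerLibrary.from_jsonl(lib.to_jsonl())
        assert len(again) == len(lib)
        g = GenericPosition.from_token("45x50")
        a = lib.lookup(g, "C")[0]
        b = again.lookup(g, "C")[0]
        assert np.allclose(a.backbone_frame, b.backbone_frame)
        assert dict(a.sidechain_atoms).keys() == dict(b.sidechain_atoms).keys()


class TestApplyRotamer:
    def test_self_donor_is_noop(self, toy):
        structure, _, _ = toy
        model = structure.copy()
        lib = build_library([structure])
        g = GenericPosition.from_token("5x50")
        aa = model.by_generic()[g].amino_acid
        before = {k: v.copy() for k, v in model.by_generic()[g].atoms.items()}
        donor = apply_rotamer(model, g, aa, lib)
        assert donor == structure.id
        after = model.by_generic()[g].atoms
        for name, xyz in before.items():
            assert np.allclose(after[name], xyz, atol=1e-9)

    def test_backbone_bit_identical_after_retype(self, toy):
        """Applying a lysine rotamer at a position the model currently types
        as leucine swaps the sidechain atom set but leaves every backbone
        coordinate untouched."""
        structure, _, _ = toy
        model = structure.copy()
        lys = next(
            r for r in structure.residues if r.amino_acid == "K" and r.generic
        )
        target_res = model.by_generic()[lys.generic]
        # re-type the model residue to leucine (placeholder sidechain)
        target_res.amino_acid = "L"
        target_res.atoms = {
            k: v for k, v in target_res.atoms.items() if k in ("N", "CA", "C", "O", "CB")
        }
        lib = build_library([structure])
        before_backbone = {
            k: v.copy() for k, v in target_res.atoms.items() if k in ("N", "CA", "C", "O")
        }
        donor = apply_rotamer(model, lys.generic, "K", lib)
        assert donor == structure.id
        res = model.by_generic()[lys.generic]
        assert res.amino_acid == "K"
        assert set(res.sidechain_atoms()) == {"CB", "CG", "CD", "CE", "NZ"}
        for name, xyz in before_backbone.items():
            assert np.array_equal(res.atoms[name], xyz)

    def test_twin_library_recovers_ground_truth_sidechains(self, spec, toy):
        """With a library built from an intact twin, every applied sidechain
        lands within 0.01 Å of the twin's own atoms."""
        structure, _, _ = toy
        twin = structure.copy()
        twin.id = "TWIN"
        lib = build_library([twin])
        model = structure.copy()
        checked = 0
        for r in structure.residues:
            if r.generic is None or r.amino_acid == "G":
                continue
            if apply_rotamer(model, r.generic, r.amino_acid, lib) is None:
                continue
            got = model.by_generic()[r.generic].sidechain_atoms()
            want = twin.by_generic()[r.generic].sidechain_atoms()
            for name, xyz in want.items():
                assert np.linalg.norm(got[name] - xyz) < 0.01
            checked += 1
        assert checked > 100

    def test_missing_entry_flags_residue(self, toy):
        structure, _, _ = toy
        model = structure.copy()
        g = GenericPosition.from_token("5x50")
        donor = apply_rotamer(model, g, "W", RotamerLibrary())
        assert donor is None
        assert "low_confidence" in model.by_generic()[g].flags


class TestRevertMutations:
    def make_catalog(self, spec, mutated_tokens, library_gap_token=None):
        defects = [
            ("mutate", {"token": t, "new_aa": "W"}) for t in mutated_tokens
        ]
        variants = [{"id": "MUT01", "defects": defects}]
        if library_gap_token:
            variants.append(
                {"id": "GAPPY", "defects": [("drop_sidechain", {"token": library_gap_token})]}
            )
        return make_template_catalog(spec, variants)

    def test_empty_mutation_list_unchanged(self, spec, toy):
        structure, _, ann = toy
        model = structure.copy()
        lib = build_library([structure])
        _, log = revert_construct_mutations(model, ann, lib)
        assert log == []

    def test_all_mutations_reverted(self, spec):
        tokens = ("2x50", "4x47", "6x48")
        cat = self.make_catalog(spec, tokens)
        intact, seq, _ = generate_toy_receptor(spec)
        mutated, mut_ann = cat[1]
        lib = build_library([intact])
        model = mutated.copy()
        _, log = revert_construct_mutations(model, mut_ann, lib)
        assert len(log) == 3
        for tok in tokens:
            g = GenericPosition.from_token(tok)
            assert model.by_generic()[g].amino_acid == seq.by_generic()[g].amino_acid
            assert "engineered_mutation" not in model.by_generic()[g].flags

    def test_library_gap_flagged_not_silent(self, spec):
        tokens = ("2x50", "4x47", "6x48")
        cat = self.make_catalog(spec, tokens)
        mutated, mut_ann = cat[1]
        intact, seq, _ = generate_toy_receptor(spec)
        # library without any entry at 6x48: remove it from the only source
        donor = intact.copy()
        g_gap = GenericPosition.from_token("6x48")
        donor.residues.remove(donor.by_generic()[g_gap])
        lib = build_library([donor])
        model = mutated.copy()
        _, log = revert_construct_mutations(model, mut_ann, lib)
        outcomes = dict(log)
        assert outcomes["6x48"] is None
        assert "low_confidence" in model.by_generic()[g_gap].flags
        reverted = [t for t in tokens if outcomes[t] is not None]
        assert len(reverted) == 2


class TestChimericIdentity:
    def test_no_rotamers_raw_equals_chimeric(self, toy):
        structure, seq, _ = toy
        raw, chim = chimeric_identity(seq, structure)
        assert raw == chim

    def test_saturated_library_reaches_100(self, spec, toy):
        structure, seq, _ = toy
        model, _, _ = generate_toy_receptor(
            dataclasses.replace(
                spec, structure_id="DIV", defects=(("diverge", {"n": 15}),)
            )
        )
        original = {r.author_number: r.amino_acid for r in model.residues}
        lib = build_library([structure])  # covers every target amino acid
        for r in list(model.residues):
            if r.generic is None:
                continue
            want = seq.by_generic().get(r.generic)
            if want is None or r.amino_acid == want.amino_acid:
                continue
            if want.amino_acid == "G":
                r.atoms = {k: v for k, v in r.atoms.items() if k in ("N", "CA", "C", "O")}
                r.amino_acid = "G"
            else:
                assert apply_rotamer(model, r.generic, want.amino_acid, lib)
        raw, chim = chimeric_identity(seq, model, original)
        assert raw < 100.0
        assert chim == pytest.approx(100.0)
        assert chim >= raw
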