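"""Template ranking vs a brute-force dominance oracle, and loop selection."""

import dataclasses

import numpy as np
import pytest

from gpcrgraft.templates import (
    TemplateScore,
    order_scores,
    rank_main_templates,
    select_segment_template,
)
from gpcrgraft.toys import ToySpec, generate_toy_receptor, make_template_catalog
from gpcrgraft.types import SelectionError


def brute_force_order(scores):
    """Independent oracle: selection sort with an explicit criterion chain."""

    def better(a: TemplateScore, b: TemplateScore) -> bool:
        if a.class_rank != b.class_rank:
            return a.class_rank < b.class_rank
        if a.state_match != b.state_match:
            return a.state_match
        sa, sb = round(a.similarity_pct * 10), round(b.similarity_pct * 10)
        if sa != sb:
            return sa > sb
        if a.coverage != b.coverage:
            return a.coverage > b.coverage
        if a.resolution != b.resolution:
            return a.resolution < b.resolution
        return a.structure_id < b.structure_id

    remaining = list(scores)
    out = []
    while remaining:
        best = remaining[0]
        for cand in remaining[1:]:
            if better(cand, best):
                best = cand
        remaining.remove(best)
        out.append(best)
    return out


def random_scores(rng, n):
    return [
        TemplateScore(
            structure_id=f"S{i:02d}",
            class_rank=int(rng.integers(0, 2)),
            state_match=bool(rng.integers(0, 2)),
            similarity_pct=float(np.round(rng.uniform(20, 100), 1)),
            coverage=int(rng.integers(100, 160)),
            resolution=float(np.round(rng.uniform(1.5, 4.0), 1)),
        )
        for i in range(n)
    ]


class TestOrdering:
    def test_resolution_breaks_final_tie(self):
        a = TemplateScore("A", 0, True, 50.0, 100, 2.0)
        b = TemplateScore("B", 0, True, 50.0, 100, 3.0)
        assert order_scores([b, a]) == [a, b]

    def test_class_outranks_similarity(self):
        same_class = TemplateScore("A", 0, True, 40.0, 100, 2.5)
        fallback = TemplateScore("B", 1, True, 90.0, 150, 1.8)
        assert order_scores([fallback, same_class])[0] is same_class

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            scores = random_scores(rng, int(rng.integers(2, 7)))
            assert order_scores(scores) == brute_force_order(scores)

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(9)
        scores = random_scores(rng, 6)
        first = order_scores(scores)
        for _ in range(5):
            shuffled = list(scores)
            rng.shuffle(shuffled)
            assert order_scores(shuffled) == first

    def test_dominance_never_violated(self):
        """A candidate at least as good everywhere and strictly better
        somewhere is never ranked below the dominated one."""
        rng = np.random.default_rng(13)
        for _ in range(40):
            scores = random_scores(rng, 5)
            ordered = order_scores(scores)
            pos = {s.structure_id: i for i, s in enumerate(ordered)}
            for a in scores:
                for b in scores:
                    if a is b:
                        continue
                    dominates = (
                        a.class_rank <= b.class_rank
                        and a.state_match >= b.state_match
                        and a.similarity_pct >= b.similarity_pct
                        and a.coverage >= b.coverage
                        and a.resolution <= b.resolution
                        and (
                            a.class_rank < b.class_rank
                            or a.state_match > b.state_match
                            or a.similarity_pct > b.similarity_pct
                            or a.coverage > b.coverage
                            or a.resolution < b.resolution
                        )
                    )
                    if dominates:
                        assert pos[a.structure_id] < pos[b.structure_id]


class TestRankMainTemplates:
    def test_empty_catalog_error(self, intact_toy):
        _, seq, _ = intact_toy
        with pytest.raises(SelectionError):
            rank_main_templates(seq, [], "inactive")

    def test_no_desired_state_error(self, base_spec, intact_toy):
        _, seq, _ = intact_toy
        catalog = make_template_catalog(
            dataclasses.replace(base_spec, state="active"), []
        )
        with pytest.raises(SelectionError, match="inactive"):
            rank_main_templates(seq, catalog, "inactive")

    def test_same_receptor_ranks_first(self, base_spec, intact_toy):
        _, seq, _ = intact_toy
        catalog = make_template_catalog(
            base_spec,
            [{"id": "FAR", "receptor": "OTHER", "defects": [("diverge", {"n": 25})]}],
        )
        ranked = rank_main_templates(seq, catalog, "inactive")
        assert ranked[0].structure_id == base_spec.structure_id

    def test_class_fallback_b2_to_b1(self, base_spec):
        _, seq, _ = generate_toy_receptor(
            dataclasses.replace(base_spec, gpcr_class="B2")
        )
        catalog = make_template_catalog(
            dataclasses.replace(base_spec, gpcr_class="B1"), []
        )
        ranked = rank_main_templates(seq, catalog, "inactive")
        assert ranked[0].class_rank == 1


class TestSelectSegmentTemplate:
    def test_no_length_equal_candidate_returns_none(self, base_spec, intact_toy):
        _, seq, _ = intact_toy
        catalog = make_template_catalog(base_spec, [])
        n = len(seq.segment_residues("ICL1"))
        assert (
            select_segment_template("ICL1", n + 2, catalog, seq, True) is None
        )

    def test_higher_similarity_wins(self, base_spec, intact_toy):
        _, seq, _ = intact_toy
        catalog = make_template_catalog(
            base_spec,
            [
                {"id": "NEAR", "receptor": "N1", "defects": [("diverge", {"n": 5})]},
                {"id": "FARAWAY", "receptor": "F1", "defects": [("diverge", {"n": 30})]},
            ],
        )[1:]
        n = len(seq.segment_residues("ICL1"))
        choice = select_segment_template("ICL1", n, catalog, seq, True)
        assert choice.structure_id == "NEAR"

    def test_incomplete_backbone_excluded(self, base_spec, intact_toy):
        _, seq, _ = intact_toy
        catalog = make_template_catalog(
            base_spec,
            [{"id": "NOLOOP", "defects": [("delete_segment", {"segment": "ICL1"})]}],
        )[1:]
        n = len(seq.segment_residues("ICL1"))
        assert select_segment_template("ICL1", n, catalog, seq, True) is None

    def test_choice_equals_exhaustive_check(self, base_spec, intact_toy):
        """4 candidates with mixed resolutions: the pick is the survivor
        with lexicographically best (similarity, coverage, resolution)."""
        _, seq, _ = intact_toy
        variants = [
            {"id": f"C{i}", "receptor": f"R{i}",
             "resolution": res, "defects": [("diverge", {"n": div})]}
            for i, (res, div) in enumerate([(2.0, 12), (1.6, 12), (3.0, 4), (2.4, 20)])
        ]
        catalog = make_template_catalog(base_spec, variants)[1:]
        n = len(seq.segment_residues("ECL3"))
        choice = select_segment_template("ECL3", n, catalog, seq, True)

        # exhaustive oracle over the candidates
        from gpcrgraft.alignment import align_by_generic

        best = None
        for structure, ann in catalog:
            residues = structure.segment_residues("ECL3")
            if len(residues) != n or not all(r.has_backbone for r in residues):
                continue
            sim = align_by_generic(seq, structure).similarity_pct
            cov = len(structure.generic_positions(backbone_only=True))
            key = (-round(sim * 10), -cov, ann.resolution, ann.structure_id)
            if best is None or key < best[0]:
                best = (key, ann.structure_id)
        assert choice.structure_id == best[1]
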