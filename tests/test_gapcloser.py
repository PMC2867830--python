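import numpy as np
import pytest

from refscaf.gapcloser import (CloseParams, Junction, close_layout,
                               fill_from_draft, place_unplaced_into_gaps,
                               resolve_overlap, screen_contained)
from refscaf.refguided import ReferenceGuidedDraft
from refscaf.scaffolder import Scaffold, place_scaffolds
from refscaf.seqio import revcomp
from refscaf.synthetic import ShredPolicy, random_genome, shred_to_scaffolds

from conftest import mutate_snps, random_dna
from oracles import longest_overlap


def perfect_draft(seq, ref_id="reference"):
    return ReferenceGuidedDraft(seq, np.full(len(seq), 93, dtype=np.int64),
                                np.ones(len(seq), dtype=bool), ref_id)


class TestResolveOverlap:
    def test_constructed_exact_overlap(self, rng):
        x, s, y = random_dna(rng, 300), random_dna(rng, 50), random_dna(rng, 300)
        merged, ov = resolve_overlap(x + s, s + y, min_overlap=30)
        assert ov == 50
        assert merged == x + s + y
        assert len(merged) == 350 + 350 - 50

    def test_disjoint_sequences_no_overlap(self, rng):
        assert resolve_overlap(random_dna(rng, 400), random_dna(rng, 400)) is None

    def test_single_mismatch_found_where_oracle_says(self, rng):
        x, y = random_dna(rng, 200), random_dna(rng, 200)
        s = random_dna(rng, 60)
        s_mut = list(s)
        s_mut[30] = "ACGT"[("ACGT".index(s[30]) + 1) % 4]
        s_mut = "".join(s_mut)
        left, right = x + s, s_mut + y
        got = resolve_overlap(left, right, 30, 0.05)
        expect = longest_overlap(left, right, 30, 0.05)
        assert got is not None and got[1] == expect == 60

    @pytest.mark.parametrize("seed", range(10))
    def test_randomized_equals_all_offsets_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ov_true = int(rng.integers(0, 120))
        left = random_dna(rng, int(rng.integers(150, 400)))
        right = mutate_snps(rng, left[-ov_true:], 0.01) + \
            random_dna(rng, int(rng.integers(100, 300))) if ov_true else \
            random_dna(rng, 200)
        got = resolve_overlap(left, right, 30, 0.02)
        expect = longest_overlap(left, right, 30, 0.02)
        if expect is None:
            assert got is None
        else:
            assert got is not None and got[1] == expect

    def test_mismatch_resolution_prefers_interior_base(self):
        left = "A" * 100 + "ACGTACGTACGTACGTACGTACGTACGTACGT"
        right = "ACGTACGTACGTACGTACGTACGTACGTACGT" + "T" * 100
        # plant one disagreement near the right edge of the overlap
        right = right[:30] + "A" + right[31:]
        merged, ov = resolve_overlap(left, right, 30, 0.05)
        assert ov == 32
        # position 30 of the overlap is closer to left's end -> right's base wins
        assert merged[100 + 30] == "A"


class TestFillFromDraft:
    def test_fully_confident_interval_spliced(self, rng):
        genome = random_dna(rng, 10_000)
        draft = perfect_draft(genome)
        left, right = genome[:4000], genome[4200:8000]
        got = fill_from_draft(left, right, draft)
        assert got is not None
        insert, interval = got
        assert insert == genome[4000:4200] and interval == (4000, 4200)
        assert left + insert + right == genome[:8000]

    def test_masked_base_blocks_filling(self, rng):
        genome = random_dna(rng, 10_000)
        draft = perfect_draft(genome)
        draft.confident_mask[4100] = False
        assert fill_from_draft(genome[:4000], genome[4200:8000], draft) is None

    def test_out_of_order_ends_rejected(self, rng):
        genome = random_dna(rng, 10_000)
        draft = perfect_draft(genome)
        # "left" scaffold actually lies downstream of "right": rearrangement
        assert fill_from_draft(genome[6000:9000], genome[1000:4000], draft) is None

    def test_ambiguous_terminus_in_repeat_rejected(self, rng):
        unit = random_dna(rng, 1500)
        genome = unit + random_dna(rng, 2000) + unit + random_dna(rng, 2000)
        draft = perfect_draft(genome)
        # left scaffold ends inside the repeated unit: two equal loci
        left = random_dna(rng, 500) + unit[:1200]
        right = genome[5200:6500]
        assert fill_from_draft(left, right, draft) is None


def layout_for(scaffolds, reference, **kw):
    return place_scaffolds([Scaffold(i, s) for i, s in scaffolds.items()],
                           reference, **kw)


class TestCloseLayout:
    def test_overlap_round_trip_exact(self):
        genome = random_genome(50_000, seed=31)
        policy = ShredPolicy(n_random_breaks=9, overlap_bp=50,
                             revcomp_fraction=0.3)
        scaffolds, _ = shred_to_scaffolds(genome, policy, seed=31)
        layout = layout_for(scaffolds, genome)
        final = close_layout(layout, scaffolds)
        assert final.sequence == genome
        assert final.census["overlap_merged"] == len(layout.placements) - 1

    def test_draft_fill_round_trip_exact(self):
        genome = random_genome(50_000, seed=32)
        policy = ShredPolicy(n_random_breaks=9, gap_bp=(100, 300))
        scaffolds, _ = shred_to_scaffolds(genome, policy, seed=32)
        layout = layout_for(scaffolds, genome)
        final = close_layout(layout, scaffolds, perfect_draft(genome))
        assert final.sequence == genome
        assert final.census["draft_filled"] == len(layout.placements) - 1

    def test_no_draft_no_overlap_all_open(self):
        genome = random_genome(30_000, seed=33)
        policy = ShredPolicy(n_random_breaks=5, gap_bp=150)
        scaffolds, truth = shred_to_scaffolds(genome, policy, seed=33)
        layout = layout_for(scaffolds, genome)
        final = close_layout(layout, scaffolds)
        n = len(layout.placements)
        assert final.census["open"] == n - 1
        assert len(final.gaps) == n - 1
        # removing N-runs reproduces the oriented scaffolds in order
        parts = [p for p in final.sequence.split("N") if p]
        expected = [scaffolds[row["id"]] for row in truth]
        assert parts == expected

    def test_open_gap_sized_by_reference_distance(self):
        genome = random_genome(30_000, seed=34)
        policy = ShredPolicy(n_random_breaks=5, gap_bp=500)
        scaffolds, truth = shred_to_scaffolds(genome, policy, seed=34)
        layout = layout_for(scaffolds, genome)
        final = close_layout(layout, scaffolds)
        for g, (a, b) in zip(final.gaps, zip(truth, truth[1:])):
            assert g.estimated_size == b["start"] - a["end"] == g.end - g.start

    def test_idempotent_on_single_scaffold(self):
        genome = random_genome(5000, seed=35)
        layout = layout_for({"only": genome}, genome)
        final = close_layout(layout, {"only": genome})
        assert final.sequence == genome and final.junctions == []

    def test_census_conservation_mixed_modes(self):
        genome = random_genome(40_000, seed=36)
        policy = ShredPolicy(n_random_breaks=7, gap_bp=(50, 400))
        scaffolds, _ = shred_to_scaffolds(genome, policy, seed=36)
        layout = layout_for(scaffolds, genome)
        draft = perfect_draft(genome)
        draft.confident_mask[20_000:21_000] = False   # one region unfillable
        final = close_layout(layout, scaffolds, draft)
        c = final.census
        assert sum(c.values()) == len(layout.placements) - 1
        assert c["open"] >= 0 and c["draft_filled"] >= 1

    def test_mask_growth_never_loses_draft_fills(self):
        genome = random_genome(40_000, seed=37)
        policy = ShredPolicy(n_random_breaks=7, gap_bp=200)
        scaffolds, _ = shred_to_scaffolds(genome, policy, seed=37)
        layout = layout_for(scaffolds, genome)
        rng = np.random.default_rng(37)
        draft = perfect_draft(genome)
        draft.confident_mask[rng.random(len(genome)) < 0.005] = False
        fills_masked = close_layout(layout, scaffolds, draft).census["draft_filled"]
        fills_full = close_layout(layout, scaffolds,
                                  perfect_draft(genome)).census["draft_filled"]
        assert fills_full >= fills_masked

    def test_reference_mismatch_rejected(self):
        genome = random_genome(20_000, seed=38)
        policy = ShredPolicy(n_random_breaks=3, gap_bp=100)
        scaffolds, _ = shred_to_scaffolds(genome, policy, seed=38)
        layout = layout_for(scaffolds, genome, reference_id="chr1")
        with pytest.raises(ValueError, match="chr1"):
            close_layout(layout, scaffolds, perfect_draft(genome, "other"))


class TestJunctionInvariants:
    def test_detail_must_match_status(self):
        with pytest.raises(ValueError):
            Junction("a", "b", "overlap_merged", estimated_gap=10)
        with pytest.raises(ValueError):
            Junction("a", "b", "open", overlap_len=3, estimated_gap=10)


class TestScreens:
    def test_excerpt_and_its_revcomp_contained(self):
        genome = random_genome(20_000, seed=39)
        layout = layout_for({"whole": genome}, genome)
        final = close_layout(layout, {"whole": genome})
        probes = [Scaffold("fwd", genome[3000:3500]),
                  Scaffold("rev", revcomp(genome[8000:8500])),
                  Scaffold("alien", random_genome(500, seed=40))]
        assert screen_contained(probes, final) == ["fwd", "rev"]

    def test_unplaced_suggested_for_matching_gap_flank(self):
        genome = random_genome(30_000, seed=41)
        policy = ShredPolicy(n_random_breaks=4, gap_bp=1200)
        scaffolds, truth = shred_to_scaffolds(genome, policy, seed=41)
        layout = layout_for(scaffolds, genome)
        final = close_layout(layout, scaffolds)
        assert final.gaps
        gap = final.gaps[0]
        a, b = truth[0], truth[1]
        # an IS-like unplaced scaffold whose start overlaps the left flank
        filler = Scaffold("filler", genome[a["end"] - 60:b["start"] + 60])
        plasmid = Scaffold("plasmid", random_genome(2000, seed=42))
        suggestions, no_anchor = place_unplaced_into_gaps(
            [filler, plasmid], final, CloseParams(min_overlap=30))
        assert any(s["scaffold_id"] == "filler" and s["gap_index"] == 0
                   for s in suggestions)
        assert no_anchor == ["plasmid"]
        assert all(s["scaffold_id"] != "plasmid" for s in suggestions)
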