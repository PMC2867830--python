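from collections import Counter

import numpy as np
import pytest

from refscaf.refguided import (Alignment, ConsensusParams, ReadPair,
                               _consensus_arrays, alignments_to_sam,
                               build_draft, call_consensus_base,
                               map_reads_naive, mapping_report, parse_sam,
                               pileup, remap_validation)
from refscaf.seqio import revcomp
from refscaf.synthetic import random_genome, simulate_reads

from conftest import random_dna
from oracles import expand_pileup

Q35 = chr(35 + 33) * 36


def make_pair(pid, s1, s2):
    return ReadPair(pid, s1, s2, chr(68) * len(s1), chr(68) * len(s2))


class TestMapReadsNaive:
    def test_error_free_reads_map_at_true_positions(self):
        genome = random_genome(20_000, seed=1)
        pairs, truth = simulate_reads(genome, fold_coverage=3, seed=1)
        alignments = map_reads_naive(pairs, genome)
        assert all(a.is_mapped for a in alignments)
        for a in alignments:
            mate = 1 if a.flag & 64 else 2
            pos, strand = truth.read_map[f"{a.read_id}/{mate}"]
            assert a.pos == pos
            assert bool(a.flag & 16) == (strand == "reverse")

    def test_pure_n_read_unmapped(self):
        genome = random_genome(2000, seed=2)
        pair = make_pair("n", "N" * 36, genome[100:136])
        a1, a2 = map_reads_naive([pair], genome)
        assert not a1.is_mapped and a2.is_mapped

    def test_single_substitution_matches_exhaustive_scan(self):
        """Placement of 1-error reads equals the brute-force argmax position."""
        rng = np.random.default_rng(3)
        genome = random_genome(5000, seed=3)
        for _ in range(30):
            pos = int(rng.integers(0, 5000 - 40))
            read = list(genome[pos:pos + 40])
            i = int(rng.integers(0, 40))
            read[i] = "ACGT"[("ACGT".index(read[i]) + 1) % 4]
            read = "".join(read)
            # oracle: best forward-strand score over all positions
            scores = [sum(a == b for a, b in zip(read, genome[p:p + 40]))
                      for p in range(5000 - 39)]
            best = int(np.argmax(scores))
            aln = map_reads_naive([make_pair("r", read, read)], genome)[0]
            assert aln.is_mapped
            if not aln.multi:
                assert aln.pos == best == pos

    def test_repeat_read_flagged_multimapping(self):
        unit = random_dna(np.random.default_rng(4), 500)
        genome = unit + random_dna(np.random.default_rng(5), 1000) + unit
        read = unit[100:136]
        aln = map_reads_naive([make_pair("r", read, read)], genome)[0]
        assert aln.is_mapped and aln.multi and aln.mapq == 0

    def test_sam_round_trip_through_pysam(self, tmp_path):
        genome = random_genome(3000, seed=6)
        pairs, _ = simulate_reads(genome, fold_coverage=2, seed=6)
        alignments = map_reads_naive(pairs, genome)
        sam = tmp_path / "out.sam"
        sam.write_text(alignments_to_sam(alignments, "ref", len(genome)))
        back = parse_sam(sam)
        assert len(back) == len(alignments)
        for a, b in zip(alignments, back):
            assert (a.read_id, a.flag, a.pos, a.seq, a.cigar) == \
                (b.read_id, b.flag, b.pos, b.seq, b.cigar)


class TestPileup:
    def test_three_reads_one_column(self):
        ref = "ACGTACGTACGT"
        alns = [Alignment("r%d" % i, 0, 4, "ACGT", (30, 31, 32, 33), "4M")
                for i in range(3)]
        pile = pileup(alns, ref)
        assert pile.columns[4] == [("A", 30)] * 3
        assert pile.columns[0] == []

    def test_no_reads_all_empty(self):
        pile = pileup([], "ACGT" * 10)
        assert pile.n_observations == 0

    def test_deletion_contributes_gap_observations(self):
        ref = "ACGTACGTAC"
        a = Alignment("r", 0, 0, "ACGTGTAC", (30,) * 8, "4M2D4M")
        pile = pileup([a], ref)
        assert pile.columns[4] == [("-", 0)] and pile.columns[5] == [("-", 0)]
        assert pile.columns[6] == [("G", 30)]

    def test_insertion_does_not_shift_reference(self):
        ref = "ACGTACGTAC"
        a = Alignment("r", 0, 0, "ACGTTTACGT", (30,) * 10, "4M2I4M")
        pile = pileup([a], ref)
        assert pile.columns[4] == [("A", 30)]  # read base after the insertion

    def test_out_of_range_alignment_names_record(self):
        with pytest.raises(ValueError, match="badread"):
            pileup([Alignment("badread", 0, 8, "ACGT", (30,) * 4, "4M")],
                   "ACGTACGTAC")

    @pytest.mark.parametrize("seed", range(5))
    def test_random_columns_equal_naive_expansion(self, seed):
        genome = random_genome(2000, seed=seed)
        pairs, _ = simulate_reads(genome, fold_coverage=4, seed=seed)
        alignments = map_reads_naive(pairs, genome)
        pile = pileup(alignments, genome)
        expected = expand_pileup(alignments, len(genome))
        for i in range(len(genome)):
            assert Counter(pile.columns[i]) == Counter(expected[i])

    def test_conservation_observations_equal_aligned_bases(self):
        genome = random_genome(3000, seed=8)
        pairs, _ = simulate_reads(genome, fold_coverage=5, seed=8)
        alignments = map_reads_naive(pairs, genome)
        pile = pileup(alignments, genome)
        aligned = sum(len(a.seq) for a in alignments
                      if a.is_mapped and not a.multi)
        assert pile.n_observations == aligned


class TestConsensus:
    def test_empty_column(self):
        assert call_consensus_base([]) == ("N", 0)

    def test_unanimous_column_capped(self):
        assert call_consensus_base([("G", 30)] * 5) == ("G", 93)

    def test_mixed_column_additive_arithmetic(self):
        assert call_consensus_base([("A", 30), ("A", 30), ("C", 20)]) == ("A", 40)

    def test_tie_calls_n(self):
        assert call_consensus_base([("A", 30), ("C", 30)]) == ("N", 0)

    def test_gap_observations_count_against(self):
        assert call_consensus_base([("A", 30), ("-", 0), ("T", 25)]) == ("A", 5)

    @pytest.mark.parametrize("seed", range(5))
    def test_vectorised_path_equals_scalar_calls(self, seed):
        rng = np.random.default_rng(seed)
        from refscaf.refguided import Pileup
        pile = Pileup(50, keep_observations=True)
        for _ in range(300):
            pos = int(rng.integers(0, 50))
            base = "ACGT-N"[rng.integers(0, 6)]
            pile.add(pos, base, int(rng.integers(0, 45)))
        bases, quals = _consensus_arrays(pile)
        for i in range(50):
            b, q = call_consensus_base(pile.columns[i])
            assert chr(bases[i]) == b and quals[i] == q


class TestBuildDraft:
    def test_error_free_reads_reproduce_genome_at_covered(self):
        genome = random_genome(20_000, seed=10)
        pairs, _ = simulate_reads(genome, fold_coverage=30, seed=10)
        draft = build_draft(map_reads_naive(pairs, genome), genome)
        covered = draft.quality > 0
        assert all(draft.sequence[i] == genome[i]
                   for i in np.flatnonzero(covered))
        assert draft.confident_mask.sum() >= 0.99 * len(genome)

    def test_no_reads_gives_all_n_nothing_confident(self):
        draft = build_draft([], "ACGT" * 100)
        assert set(draft.sequence) == {"N"}
        assert not draft.confident_mask.any()

    def test_homozygous_snp_recovered_confidently(self):
        genome = random_genome(5000, seed=11)
        mutant = genome[:2500] + "ACGT"[("ACGT".index(genome[2500]) + 1) % 4] \
            + genome[2501:]
        pairs, _ = simulate_reads(mutant, fold_coverage=30, seed=11)
        draft = build_draft(map_reads_naive(pairs, genome), genome)
        assert draft.sequence[2500] == mutant[2500]
        assert draft.confident_mask[2500]

    def test_raising_cutoff_never_adds_confident_positions(self):
        genome = random_genome(5000, seed=12)
        pairs, _ = simulate_reads(genome, fold_coverage=8, error_rate=0.01,
                                  seed=12)
        alignments = map_reads_naive(pairs, genome)
        confident = [
            build_draft(alignments, genome,
                        ConsensusParams(quality_cutoff=c)).confident_mask.sum()
            for c in (10, 20, 40, 60, 80)]
        assert all(a >= b for a, b in zip(confident, confident[1:]))


class TestReports:
    def test_uniform_coverage_arithmetic(self):
        ref = random_genome(1000, seed=13)
        alns = [Alignment(f"r{i}", 0, p, ref[p:p + 100], (35,) * 100, "100M")
                for i, p in enumerate(range(0, 901, 10))]
        rep = mapping_report(alns, ref)
        assert rep.mapped_fraction == 1.0
        assert rep.mean_fold_coverage == pytest.approx(len(alns) * 100 / 1000)

    def test_empty_alignments_all_zero(self):
        rep = mapping_report([], "ACGT" * 10)
        assert rep.mapped_fraction == rep.mean_fold_coverage == 0.0

    def test_q40_fraction_never_exceeds_q30(self):
        genome = random_genome(8000, seed=14)
        pairs, _ = simulate_reads(genome, fold_coverage=6, error_rate=0.01,
                                  seed=14)
        alignments = map_reads_naive(pairs, genome)
        draft = build_draft(alignments, genome)
        rep = mapping_report(alignments, genome, draft)
        assert rep.frac_q40 <= rep.frac_q30 <= 1.0
        assert rep.mean_fold_coverage > 0

    def test_remap_of_draft_reads_is_total(self):
        genome = random_genome(5000, seed=15)
        pairs, _ = simulate_reads(genome, fold_coverage=4, seed=15)
        assert remap_validation(pairs, genome) == 1.0

    def test_remap_of_unrelated_reads_is_negligible(self):
        genome = random_genome(5000, seed=16)
        other = random_genome(5000, seed=17)
        pairs, _ = simulate_reads(other, fold_coverage=4, seed=16)
        assert remap_validation(pairs, genome) < 0.01


def test_read_pair_validation():
    with pytest.raises(ValueError):
        ReadPair("x", "ACGT", "ACGT", "!!!", "!!!!")
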