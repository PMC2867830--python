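"""Desk-scale validation experiments with known ground truth.

Each experiment builds a seeded synthetic dataset at the scale the package is
exercised at (a few hundred kbp — the shape, repeat structure and read
geometry of a small bacterial finishing project, not its full size), runs the
relevant pipeline stages, and scores the result against the generator's truth
tables. These are the quantitative checks behind the test suite and the
reproduction script; all report plain dicts of numbers.
"""

from __future__ import annotations

import numpy as np

from .gapcloser import CloseParams, close_layout
from .refguided import (ConsensusParams, build_draft, map_reads_naive,
                        mapping_report, remap_validation)
from .scaffolder import Scaffold, place_scaffolds
from .synthetic import (MutationSpec, ShredPolicy, derive_genome,
                        natto_like_scenario, random_genome, shred_to_scaffolds,
                        simulate_reads)


def _identity_pct(a: str, b: str) -> float:
    if a == b:
        return 100.0
    import edlib
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 100.0 * (1 - d / max(len(a), len(b)))


def overlap_roundtrip(seed: int, length: int = 200_000, n_pieces: int = 30,
                      overlap_bp: int = 50) -> dict:
    """Shred a genome into overlapping pieces, re-place and close; score
    string identity of the reconstruction against the source genome."""
    genome = random_genome(length, seed)
    policy = ShredPolicy(n_random_breaks=n_pieces - 1, overlap_bp=overlap_bp,
                         revcomp_fraction=0.3, min_piece=2000)
    scaffolds, _ = shred_to_scaffolds(genome, policy, seed + 1)
    layout = place_scaffolds([Scaffold(i, s) for i, s in scaffolds.items()],
                             genome)
    final = close_layout(layout, scaffolds)
    return {"identity_pct": _identity_pct(final.sequence, genome),
            "n_scaffolds": len(scaffolds),
            "census": final.census,
            "exact": final.sequence == genome}


def draftfill_roundtrip(seed: int, length: int = 200_000, n_pieces: int = 30,
                        gap_range: tuple[int, int] = (100, 300),
                        fold_coverage: float = 30.0) -> dict:
    """Shred with true gaps, rebuild the gap sequence from an error-free read
    consensus, and score the reconstruction."""
    genome = random_genome(length, seed)
    policy = ShredPolicy(n_random_breaks=n_pieces - 1, gap_bp=gap_range,
                         min_piece=2000)
    scaffolds, _ = shred_to_scaffolds(genome, policy, seed + 1)
    pairs, _ = simulate_reads(genome, fold_coverage=fold_coverage,
                              seed=seed + 2)
    draft = build_draft(map_reads_naive(pairs, genome), genome,
                        ConsensusParams())
    layout = place_scaffolds([Scaffold(i, s) for i, s in scaffolds.items()],
                             genome)
    final = close_layout(layout, scaffolds, draft)
    return {"identity_pct": _identity_pct(final.sequence, genome),
            "n_scaffolds": len(scaffolds),
            "census": final.census,
            "exact": final.sequence == genome}


def placement_recovery(seed: int, length: int = 200_000, n_pieces: int = 50,
                       snp_rate: float = 0.01,
                       revcomp_fraction: float = 0.3) -> dict:
    """Order/orientation recovery of shreds of a SNP-divergent genome."""
    reference = random_genome(length, seed)
    derived, _ = derive_genome(reference, MutationSpec(
        snp_rate=snp_rate, indel_rate=0, seed=seed + 1))
    policy = ShredPolicy(n_random_breaks=n_pieces - 1,
                         revcomp_fraction=revcomp_fraction, min_piece=2000)
    scaffolds, truth = shred_to_scaffolds(derived, policy, seed + 2)
    layout = place_scaffolds([Scaffold(i, s) for i, s in scaffolds.items()],
                             reference)
    placed_order = [p.scaffold_id for p in layout.placements]
    orientations = {p.scaffold_id: p.orientation for p in layout.placements}
    correct = 0
    for i, row in enumerate(truth):
        sid = row["id"]
        if (sid in orientations and placed_order.index(sid) == i
                and orientations[sid] == row["orientation"]):
            correct += 1
    return {"accuracy_pct": 100.0 * correct / len(truth),
            "n_pieces": len(truth)}


def consensus_accuracy(seed: int, length: int = 100_000,
                       error_rate: float = 0.01,
                       fold_coverage: float = 30.0) -> dict:
    """Consensus error at confident (Q>=cutoff) positions under read errors,
    plus the error-free covered-base identity check."""
    genome = random_genome(length, seed)
    # error-free limit
    pairs0, _ = simulate_reads(genome, fold_coverage=fold_coverage,
                               seed=seed + 1)
    draft0 = build_draft(map_reads_naive(pairs0, genome), genome)
    covered = np.frombuffer(draft0.sequence.encode(), dtype=np.uint8) != ord("N")
    gbytes = np.frombuffer(genome.encode(), dtype=np.uint8)
    dbytes0 = np.frombuffer(draft0.sequence.encode(), dtype=np.uint8)
    errfree_mismatches = int((dbytes0[covered] != gbytes[covered]).sum())
    # with sequencing errors
    pairs1, _ = simulate_reads(genome, fold_coverage=fold_coverage,
                               error_rate=error_rate, seed=seed + 2)
    draft1 = build_draft(map_reads_naive(pairs1, genome), genome)
    conf = draft1.confident_mask
    dbytes1 = np.frombuffer(draft1.sequence.encode(), dtype=np.uint8)
    n_conf = int(conf.sum())
    mism = int((dbytes1[conf] != gbytes[conf]).sum())
    return {"errfree_covered_mismatches": errfree_mismatches,
            "covered_positions": int(covered.sum()),
            "confident_positions": n_conf,
            "confident_mismatch_rate": mism / n_conf if n_conf else float("nan"),
            "length": length}


def natto_like_report(seed: int, length: int = 100_000,
                      fold_coverage: float = 20.0) -> dict:
    """Full pipeline on the natto-like strain pair; mapping stats + census."""
    sc = natto_like_scenario(seed=seed, ref_length=length)
    reference, derived, truth = sc["reference"], sc["derived"], sc["truth"]
    pairs, _ = simulate_reads(derived, fold_coverage=fold_coverage,
                              seed=seed + 3)
    alignments = map_reads_naive(pairs, reference)
    draft = build_draft(alignments, reference)
    report = mapping_report(alignments, reference, draft)
    policy = ShredPolicy(at_repeats=True,
                         repeat_intervals=tuple(truth.repeat_intervals()),
                         n_random_breaks=10, overlap_bp=50,
                         revcomp_fraction=0.3)
    scaffolds, _ = shred_to_scaffolds(derived, policy, seed + 4)
    layout = place_scaffolds([Scaffold(i, s) for i, s in scaffolds.items()],
                             reference)
    final = close_layout(layout, scaffolds, draft)
    held_out, _ = simulate_reads(derived, fold_coverage=2.0, seed=seed + 5)
    remap = remap_validation(held_out, final.sequence)
    return {"mapped_pct": 100.0 * report.mapped_fraction,
            "fold_coverage": report.mean_fold_coverage,
            "q40_pct": 100.0 * report.frac_q40,
            "n_scaffolds": len(scaffolds),
            "n_placed": len(layout.placements),
            "n_unplaced": len(layout.unplaced),
            "census": final.census,
            "remap_pct": 100.0 * remap,
            "final_length": len(final.sequence)}
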