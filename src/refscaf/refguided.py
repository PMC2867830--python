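"""Reference-guided draft construction from short paired-end reads.

Short reads are placed on a close reference by exact k-mer seeding plus
ungapped extension, piled up per reference position, and reduced to a
consensus with a per-base Phred-scale confidence. Positions whose confidence
reaches the quality cutoff (default Q40) and whose depth reaches the minimum
form the *confident mask* of the draft; only those positions are trusted by
downstream gap filling.

The consensus confidence is an additive Phred vote: the called base maximises
the summed qualities of agreeing observations, and its quality is the agreeing
sum minus the disagreeing sum, floored at 0 and capped at 93. This is a
deliberately simple, monotone model — not a Bayesian genotype caller — chosen
so that every number it produces can be re-derived by hand.

Any SAM from any mapper is accepted downstream; the built-in mapper exists so
the pipeline is self-contained.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .seqio import check_dna, revcomp

MAX_PHRED = 93
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read: sequences plus Phred+33 quality strings."""

    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")
        for q in (self.qual1, self.qual2):
            vals = [ord(c) - 33 for c in q]
            if vals and not (0 <= min(vals) and max(vals) <= MAX_PHRED):
                raise ValueError(f"read {self.id}: Phred values outside [0, 93]")

    @property
    def phred1(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual1]

    @property
    def phred2(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual2]


@dataclass(frozen=True)
class ConsensusParams:
    quality_cutoff: int = 40
    min_depth: int = 1

    def __post_init__(self):
        if not (0 <= self.quality_cutoff <= MAX_PHRED):
            raise ValueError("quality_cutoff outside [0, 93]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class Alignment:
    """One aligned (or unmapped) read in SAM terms; pos is 0-based."""

    read_id: str
    flag: int
    pos: int              # -1 if unmapped
    seq: str              # as aligned (reverse-complemented for flag & 16)
    quals: tuple[int, ...]
    cigar: str = ""
    mapq: int = 60
    multi: bool = False   # equally good placements elsewhere

    @property
    def is_mapped(self) -> bool:
        return self.pos >= 0


@dataclass
class ReferenceGuidedDraft:
    """Per-base consensus over the reference with confidence and mask."""

    sequence: str
    quality: np.ndarray          # int Phred per position
    confident_mask: np.ndarray   # bool per position
    reference_id: str = "reference"

    def __post_init__(self):
        if not (len(self.sequence) == len(self.quality) == len(self.confident_mask)):
            raise ValueError("draft tracks have unequal lengths")


@dataclass(frozen=True)
class MappingReport:
    mapped_fraction: float
    mean_fold_coverage: float
    frac_q40: float
    frac_q30: float


# ---------------------------------------------------------------------------
# Naive mapping

def _kmer_index(reference: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        kmer = reference[i:i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)
    return index


def _score(read: str, reference: str, pos: int) -> int:
    return sum(a != "N" and b != "N" and a == b
               for a, b in zip(read, reference[pos:pos + len(read)]))


def _place_read(read: str, reference: str, index: dict[str, list[int]], k: int,
                min_frac: float) -> tuple[int, int, bool] | None:
    """Best ungapped placement of `read` (either strand) or None.

    Returns (pos, flag_strand_bit, multi).
    """
    L, n = len(reference), len(read)
    best_score, best = -1, []
    for strand_bit, r in ((0, read), (16, revcomp(read))):
        cands: set[int] = set()
        for off in (0, n - k):
            if off < 0:
                continue
            kmer = r[off:off + k]
            if "N" in kmer:
                continue
            for p in index.get(kmer, ()):
                start = p - off
                if 0 <= start <= L - n:
                    cands.add(start)
        for start in cands:
            s = _score(r, reference, start)
            if s > best_score:
                best_score, best = s, [(start, strand_bit)]
            elif s == best_score:
                if (start, strand_bit) not in best:
                    best.append((start, strand_bit))
    if best_score < int(np.ceil(min_frac * n)):
        return None
    best.sort()
    pos, strand_bit = best[0]
    return pos, strand_bit, len(best) > 1


def map_reads_naive(pairs: Iterable[ReadPair], reference: str, k: int = 18,
                    min_match_frac: float = 0.9) -> list[Alignment]:
    """Place each read of each pair at its best ungapped position.

    Reads with multiple equally good placements are flagged multi-mapping
    (MAPQ 0) so the consensus can exclude them; reads below the match floor
    are reported unmapped. Mates are placed independently.
    """
    reference = check_dna(reference, "reference")
    index = _kmer_index(reference, k)
    alignments: list[Alignment] = []
    for pair in pairs:
        if k > len(pair.seq1) or k > len(pair.seq2):
            raise ValueError(f"seed length {k} exceeds read length for {pair.id}")
        for mate, (seq, quals) in enumerate(
                ((pair.seq1, tuple(pair.phred1)), (pair.seq2, tuple(pair.phred2)))):
            base_flag = 1 | (64 if mate == 0 else 128)
            hit = _place_read(seq, reference, index, k, min_match_frac)
            rid = pair.id
            if hit is None:
                alignments.append(Alignment(rid, base_flag | 4, -1, seq, quals))
                continue
            pos, strand_bit, multi = hit
            aln_seq = revcomp(seq) if strand_bit else seq
            aln_quals = quals[::-1] if strand_bit else quals
            alignments.append(Alignment(rid, base_flag | strand_bit, pos, aln_seq,
                                        aln_quals, cigar=f"{len(seq)}M",
                                        mapq=0 if multi else 60, multi=multi))
    return alignments


def alignments_to_sam(alignments: Sequence[Alignment], reference_id: str,
                      reference_length: int) -> str:
    """Render alignments as SAM text with a minimal header."""
    lines = ["@HD\tVN:1.6\tSO:unsorted",
             f"@SQ\tSN:{reference_id}\tLN:{reference_length}"]
    for a in alignments:
        qstr = "".join(chr(q + 33) for q in a.quals)
        if a.is_mapped:
            fields = [a.read_id, str(a.flag), reference_id, str(a.pos + 1),
                      str(a.mapq), a.cigar, "*", "0", "0", a.seq, qstr]
        else:
            fields = [a.read_id, str(a.flag), "*", "0", "0", "*", "*", "0", "0",
                      a.seq, qstr]
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def parse_sam(path: str | Path) -> list[Alignment]:
    """Read a SAM file (any mapper) into Alignment records via pysam."""
    alignments = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            quals = tuple(rec.query_qualities) if rec.query_qualities is not None else ()
            alignments.append(Alignment(
                rec.query_name, rec.flag,
                rec.reference_start if not rec.is_unmapped else -1,
                rec.query_sequence or "", quals,
                cigar=rec.cigarstring or "", mapq=rec.mapping_quality,
                multi=rec.mapping_quality == 0))
    return alignments


# ---------------------------------------------------------------------------
# Pileup

class Pileup:
    """Per-reference-position base/quality observations.

    Always accumulates per-base Phred sums and counts (numpy, used by the
    vectorised consensus); optionally keeps the raw (base, Phred) observation
    lists for inspection and oracle tests.
    """

    def __init__(self, length: int, keep_observations: bool = True):
        self.length = length
        self.qual_sum = np.zeros((6, length), dtype=np.int64)  # A C G T - N
        self.counts = np.zeros((6, length), dtype=np.int64)
        self.columns: list[list[tuple[str, int]]] | None = (
            [[] for _ in range(length)] if keep_observations else None)

    def add(self, pos: int, base: str, qual: int) -> None:
        code = _BASE_CODE[base]
        self.qual_sum[code, pos] += qual
        self.counts[code, pos] += 1
        if self.columns is not None:
            self.columns[pos].append((base, qual))

    @property
    def n_observations(self) -> int:
        return int(self.counts.sum())

    @property
    def base_depth(self) -> np.ndarray:
        """Non-gap observation count per position (N observations included)."""
        return self.counts[[0, 1, 2, 3, 5]].sum(axis=0)


def pileup(alignments: Iterable[Alignment], reference: str,
           keep_observations: bool = True, include_multi: bool = False) -> Pileup:
    """Expand alignments into per-position columns.

    Every aligned (non-clipped, non-inserted) read base contributes to exactly
    one column; deletions contribute '-' observations at Phred 0; insertions
    are counted but do not shift reference coordinates. Multi-mapping reads
    are excluded unless `include_multi`.
    """
    L = len(reference)
    pile = Pileup(L, keep_observations=keep_observations)
    for a in alignments:
        if not a.is_mapped or (a.multi and not include_multi):
            continue
        ref_pos, read_pos = a.pos, 0
        for count, op in _CIGAR_RE.findall(a.cigar):
            n = int(count)
            if op in "M=X":
                if ref_pos + n > L:
                    raise ValueError(
                        f"alignment {a.read_id} runs past reference end "
                        f"({ref_pos + n} > {L})")
                for i in range(n):
                    q = a.quals[read_pos + i] if read_pos + i < len(a.quals) else 0
                    pile.add(ref_pos + i, a.seq[read_pos + i], q)
                ref_pos += n
                read_pos += n
            elif op == "I":
                read_pos += n      # recorded implicitly; no reference shift
            elif op == "D":
                if ref_pos + n > L:
                    raise ValueError(
                        f"alignment {a.read_id} deletion past reference end")
                for i in range(n):
                    pile.add(ref_pos + i, "-", 0)
                ref_pos += n
            elif op == "S":
                read_pos += n
            else:
                raise ValueError(
                    f"alignment {a.read_id}: unsupported CIGAR op {op!r}")
    return pile


# ---------------------------------------------------------------------------
# Consensus

def call_consensus_base(column: Sequence[tuple[str, int]],
                        params: ConsensusParams = ConsensusParams(),
                        ) -> tuple[str, int]:
    """Additive Phred vote over one column.

    The winning base maximises the summed Phred of agreeing observations; its
    quality is (agreeing sum) - (disagreeing sum, gaps and N included),
    floored at 0 and capped at 93. An empty column or a tied vote calls
    ('N', 0).
    """
    if not column:
        return "N", 0
    sums = {b: 0 for b in "ACGT"}
    total = 0
    for base, q in column:
        total += q
        if base in sums:
            sums[base] += q
    best = max(sums.values())
    if best == 0 or sum(1 for v in sums.values() if v == best) > 1:
        return "N", 0
    base = next(b for b in "ACGT" if sums[b] == best)
    return base, int(min(MAX_PHRED, max(0, best - (total - best))))


def _consensus_arrays(pile: Pileup) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised equivalent of call_consensus_base over all positions."""
    acgt = pile.qual_sum[:4]
    best_code = acgt.argmax(axis=0)
    best_sum = acgt.max(axis=0)
    total = pile.qual_sum.sum(axis=0)
    quality = np.clip(best_sum - (total - best_sum), 0, MAX_PHRED)
    tied = (acgt == best_sum).sum(axis=0) > 1
    no_call = tied | (best_sum == 0)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)[best_code].copy()
    bases[no_call] = ord("N")
    quality = np.where(no_call, 0, quality)
    return bases, quality.astype(np.int64)


def build_draft(alignments: Iterable[Alignment], reference: str,
                params: ConsensusParams = ConsensusParams(),
                reference_id: str = "reference") -> ReferenceGuidedDraft:
    """Consensus over the reference; coordinate-locked (insertions ignored)."""
    reference = check_dna(reference, "reference")
    pile = pileup(alignments, reference, keep_observations=False)
    bases, quality = _consensus_arrays(pile)
    depth = pile.base_depth
    mask = (quality >= params.quality_cutoff) & (depth >= params.min_depth)
    return ReferenceGuidedDraft(bases.tobytes().decode("ascii"), quality, mask,
                                reference_id=reference_id)


def mapping_report(alignments: Sequence[Alignment], reference: str,
                   draft: ReferenceGuidedDraft | None = None) -> MappingReport:
    """Mapping statistics: mapped fraction, fold coverage, and the fraction of
    covered consensus positions at or above Q40/Q30."""
    total = len(alignments)
    mapped = [a for a in alignments if a.is_mapped]
    aligned_bases = 0
    for a in mapped:
        for count, op in _CIGAR_RE.findall(a.cigar):
            if op in "M=X":
                aligned_bases += int(count)
    L = len(reference)
    if draft is None:
        frac_q40 = frac_q30 = 0.0
    else:
        pile = pileup(mapped, reference, keep_observations=False)
        covered = pile.base_depth > 0
        n_cov = int(covered.sum())
        q = draft.quality
        frac_q40 = float((q[covered] >= 40).sum() / n_cov) if n_cov else 0.0
        frac_q30 = float((q[covered] >= 30).sum() / n_cov) if n_cov else 0.0
    return MappingReport(
        mapped_fraction=len(mapped) / total if total else 0.0,
        mean_fold_coverage=aligned_bases / L if L else 0.0,
        frac_q40=frac_q40, frac_q30=frac_q30)


def remap_validation(pairs: Iterable[ReadPair], draft: ReferenceGuidedDraft | str,
                     k: int = 18) -> float:
    """Fraction of held-out reads the naive mapper places on the draft."""
    seq = draft.sequence if isinstance(draft, ReferenceGuidedDraft) else draft
    alignments = map_reads_naive(pairs, seq, k=k)
    if not alignments:
        return 0.0
    return sum(a.is_mapped for a in alignments) / len(alignments)
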