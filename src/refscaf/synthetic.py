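"""Synthetic genome pairs, scaffolds and paired-end reads with truth tables.

The generator emulates the structure of a natto-vs-168-like strain pair: a
reference genome, and a derived genome that differs by multi-copy insertion
sequence (IS) repeats absent from the reference, an operon-scale deletion,
and scattered SNPs and 1-bp indels. Scaffold shredding can place breakpoints
inside repeat copies, mimicking how short-read de novo assembly terminates at
repeats; read simulation produces short paired-end reads with a truncated
normal insert-size distribution.

Every operation is seeded and returns a truth record (edits applied, true
scaffold intervals and orientations, true read origins) so that recovery by
the ordering/orientation/gap-closing pipeline can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .refguided import ReadPair
from .seqio import revcomp

_BASES = "ACGT"


def random_genome(length: int, seed: int, gc: float = 0.435) -> str:
    """Random genome with the GC content typical of *Bacillus* (~43.5%)."""
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list(_BASES))[rng.choice(4, size=length, p=p)])


@dataclass(frozen=True)
class MutationSpec:
    """Differences to introduce between reference and derived genome."""

    snp_rate: float = 0.002
    indel_rate: float = 0.0002          # isolated 1-bp insertions/deletions
    is_elements: tuple[tuple[str, int], ...] = ()   # (sequence, copy_number)
    deletions: tuple[tuple[int, int], ...] = ()     # (ref position, length)
    seed: int = 0

    def __post_init__(self):
        for rate, name in ((self.snp_rate, "snp_rate"), (self.indel_rate, "indel_rate")):
            if not (0.0 <= rate <= 0.05):
                raise ValueError(f"{name} outside [0, 0.05]")
        for _, copies in self.is_elements:
            if copies < 0:
                raise ValueError("IS copy_number must be >= 0")
        ivs = sorted((p, p + ln) for p, ln in self.deletions)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("deletions overlap")


@dataclass(frozen=True)
class Edit:
    """One reference-to-derived edit.

    kind 'snp': payload is the new base; 'ins': payload is the inserted
    sequence placed before ref_pos; 'del': payload is the deleted length.
    derived_pos is where the edit lands on the derived genome.
    """

    kind: str
    ref_pos: int
    derived_pos: int
    payload: str | int
    tag: str = ""       # 'is', 'operon_deletion', 'snp', 'indel'


@dataclass
class TruthTable:
    """Ground truth linking reference, derived genome, scaffolds and reads."""

    edits: list[Edit] = field(default_factory=list)
    scaffold_map: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    read_map: dict[str, tuple[int, str]] = field(default_factory=dict)

    def replay(self, reference: str) -> str:
        """Re-apply the edit list; must reproduce the derived genome exactly."""
        out: list[str] = []
        cursor = 0
        for e in sorted(self.edits, key=lambda e: (e.ref_pos, _KIND_ORDER[e.kind])):
            out.append(reference[cursor:e.ref_pos])
            if e.kind == "del":
                cursor = e.ref_pos + int(e.payload)
            elif e.kind == "ins":
                out.append(str(e.payload))
                cursor = e.ref_pos
            elif e.kind == "snp":
                out.append(str(e.payload))
                cursor = e.ref_pos + 1
        out.append(reference[cursor:])
        return "".join(out)

    def ref_to_derived(self, pos: int) -> int | None:
        """Derived-genome coordinate of reference position `pos`.

        None when the position falls inside a deleted interval. Positions at
        an insertion point map to the coordinate after the insert.
        """
        shift = 0
        for e in sorted(self.edits, key=lambda e: (e.ref_pos, _KIND_ORDER[e.kind])):
            if e.ref_pos > pos:
                break
            if e.kind == "ins":
                shift += len(str(e.payload))
            elif e.kind == "del":
                if e.ref_pos + int(e.payload) <= pos:
                    shift -= int(e.payload)
                else:
                    return None
        return pos + shift

    def edited_ref_positions(self) -> set[int]:
        """Reference positions touched by any edit (deletions expanded)."""
        touched: set[int] = set()
        for e in self.edits:
            if e.kind == "del":
                touched.update(range(e.ref_pos, e.ref_pos + int(e.payload)))
            else:
                touched.add(e.ref_pos)
        return touched

    def repeat_intervals(self) -> list[tuple[int, int]]:
        """Derived-genome intervals occupied by inserted IS copies."""
        return [(e.derived_pos, e.derived_pos + len(str(e.payload)))
                for e in self.edits if e.kind == "ins" and e.tag == "is"]

    def deleted_intervals(self) -> list[tuple[int, int]]:
        """Reference intervals removed from the derived genome."""
        return [(e.ref_pos, e.ref_pos + int(e.payload))
                for e in self.edits if e.kind == "del" and e.tag == "operon_deletion"]


_KIND_ORDER = {"del": 0, "ins": 1, "snp": 2}


def random_is_element(length: int, seed: int) -> str:
    """A synthetic insertion-sequence element (random, fixed per seed)."""
    return random_genome(length, seed, gc=0.40)


def derive_genome(reference: str, spec: MutationSpec) -> tuple[str, TruthTable]:
    """Apply deletions, IS insertions, then point edits; return genome + truth.

    Edit positions never collide: point edits avoid deleted intervals and
    insertion points, so replaying the edit list in (ref_pos, del<ins<snp)
    order reproduces the derived genome byte-exactly.
    """
    rng = np.random.default_rng(spec.seed)
    L = len(reference)
    blocked = np.zeros(L, dtype=bool)
    edits: list[Edit] = []

    for pos, ln in spec.deletions:
        if pos + ln > L:
            raise ValueError("deletion runs past the reference end")
        blocked[pos:pos + ln] = True
        edits.append(Edit("del", pos, -1, ln, tag="operon_deletion"))

    # IS copies inserted at uniform positions outside deleted intervals
    for element, copies in spec.is_elements:
        placed = 0
        while placed < copies:
            pos = int(rng.integers(1, L - 1))
            if blocked[pos] or blocked[pos - 1]:
                continue
            blocked[pos] = True    # one insertion point per position
            edits.append(Edit("ins", pos, -1, element, tag="is"))
            placed += 1

    free = np.flatnonzero(~blocked)
    n_snp = rng.binomial(len(free), spec.snp_rate)
    n_indel = rng.binomial(len(free), spec.indel_rate)
    pick = rng.choice(len(free), size=min(n_snp + n_indel, len(free)), replace=False)
    snp_pos, indel_pos = free[pick[:n_snp]], free[pick[n_snp:]]
    for pos in sorted(int(p) for p in snp_pos):
        old = reference[pos]
        new = _BASES[(_BASES.index(old) + int(rng.integers(1, 4))) % 4] \
            if old in _BASES else "A"
        edits.append(Edit("snp", pos, -1, new, tag="snp"))
    for pos in sorted(int(p) for p in indel_pos):
        if rng.random() < 0.5:
            edits.append(Edit("ins", pos, -1, _BASES[rng.integers(4)], tag="indel"))
        else:
            edits.append(Edit("del", pos, -1, 1, tag="indel"))

    edits.sort(key=lambda e: (e.ref_pos, _KIND_ORDER[e.kind]))
    # single replay pass assigning derived positions
    out: list[str] = []
    cursor = 0
    derived_len = 0
    final_edits: list[Edit] = []
    for e in edits:
        chunk = reference[cursor:e.ref_pos]
        out.append(chunk)
        derived_len += len(chunk)
        dpos = derived_len
        if e.kind == "del":
            cursor = e.ref_pos + int(e.payload)
        elif e.kind == "ins":
            out.append(str(e.payload))
            derived_len += len(str(e.payload))
            cursor = e.ref_pos
        else:
            out.append(str(e.payload))
            derived_len += 1
            cursor = e.ref_pos + 1
        final_edits.append(replace(e, derived_pos=dpos))
    out.append(reference[cursor:])
    derived = "".join(out)
    truth = TruthTable(edits=final_edits)
    assert truth.replay(reference) == derived
    return derived, truth


@dataclass(frozen=True)
class ShredPolicy:
    """How to cut a genome into scaffold-like pieces."""

    at_repeats: bool = False
    repeat_intervals: tuple[tuple[int, int], ...] = ()
    n_random_breaks: int = 0
    overlap_bp: int = 0      # true overlap shared by consecutive pieces
    # true unsampled gap between consecutive pieces: fixed, or (lo, hi) drawn
    # uniformly per junction
    gap_bp: int | tuple[int, int] = 0
    revcomp_fraction: float = 0.0
    min_piece: int = 200


def shred_to_scaffolds(genome: str, policy: ShredPolicy, seed: int,
                       ) -> tuple[dict[str, str], list[dict]]:
    """Cut the genome into pieces; return shuffled scaffolds + truth layout.

    With `at_repeats`, one breakpoint is placed inside each repeat copy (so
    repeats terminate scaffolds, the dominant fragmentation mode of short-read
    assemblies); `n_random_breaks` adds uniform breakpoints. Consecutive
    pieces either share `overlap_bp` of true sequence or are separated by
    `gap_bp` of unsampled sequence. Breakpoints closer than `min_piece` are
    dropped. The truth layout lists pieces in genomic order with their derived
    intervals and orientations; the returned scaffold dict is shuffled.
    """
    gap_lo, gap_hi = (policy.gap_bp if isinstance(policy.gap_bp, tuple)
                      else (policy.gap_bp, policy.gap_bp))
    if policy.overlap_bp and gap_hi:
        raise ValueError("choose either overlap_bp or gap_bp, not both")
    rng = np.random.default_rng(seed)
    L = len(genome)
    accepted: list[int] = []
    # breaks must be far enough apart that gap trimming still leaves pieces
    # of at least min_piece
    spacing = policy.min_piece + gap_hi

    def admit(b: int) -> bool:
        if not (spacing <= b <= L - spacing):
            return False
        if any(abs(b - x) < spacing for x in accepted):
            return False
        accepted.append(b)
        return True

    if policy.at_repeats:
        for s, e in policy.repeat_intervals:
            admit((s + e) // 2)
    if policy.n_random_breaks:
        # oversample so spacing rejections still leave the requested count
        candidates = rng.integers(1, L - 1, size=8 * policy.n_random_breaks)
        want = len(accepted) + policy.n_random_breaks
        for b in candidates:
            if len(accepted) >= want:
                break
            admit(int(b))
    points = [0] + sorted(accepted) + [L]

    layout: list[dict] = []
    pieces: list[tuple[str, str]] = []
    n = len(points) - 1
    width = len(str(n))
    for i in range(n):
        start, end = points[i], points[i + 1]
        if i < n - 1:
            if policy.overlap_bp:
                end = min(L, end + policy.overlap_bp)
            elif gap_hi:
                gap = int(rng.integers(gap_lo, gap_hi + 1))
                end = max(start + 1, end - gap)
        orientation = "reverse" if rng.random() < policy.revcomp_fraction else "forward"
        name = f"scaffold_{i:0{width}d}"
        seq = genome[start:end]
        if orientation == "reverse":
            seq = revcomp(seq)
        layout.append({"id": name, "start": start, "end": end,
                       "orientation": orientation})
        pieces.append((name, seq))
    order = rng.permutation(len(pieces))
    scaffolds = {pieces[i][0]: pieces[i][1] for i in order}
    return scaffolds, layout


def simulate_reads(genome: str, read_len: int = 36, insert_mean: float = 163.0,
                   insert_sd: float = 15.0, fold_coverage: float = 30.0,
                   error_rate: float = 0.0, seed: int = 0, base_quality: int = 35,
                   ) -> tuple[list[ReadPair], TruthTable]:
    """Simulate paired-end reads with a truncated normal insert size.

    The pair count is ceil(fold_coverage * |genome| / (2 * read_len)). Inserts
    are truncated below at read_len (and above at the genome length);
    substitution errors are i.i.d. per base. Qualities are a constant Phred
    so consensus arithmetic stays transparent.
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    if read_len > L:
        raise ValueError("read length exceeds genome length")
    n_pairs = math.ceil(fold_coverage * L / (2 * read_len))
    inserts = rng.normal(insert_mean, insert_sd, size=n_pairs)
    inserts = np.clip(np.rint(inserts), read_len, L).astype(np.int64)
    starts = rng.integers(0, L - inserts + 1)
    flip = rng.random(n_pairs) < 0.5
    qual_str = chr(base_quality + 33) * read_len
    err_mask = (rng.random((n_pairs, 2, read_len)) < error_rate
                if error_rate > 0 else None)
    shifts = rng.integers(1, 4, size=(n_pairs, 2, read_len)) if error_rate > 0 else None

    pairs: list[ReadPair] = []
    truth = TruthTable()
    for i in range(n_pairs):
        start, ins = int(starts[i]), int(inserts[i])
        fwd = genome[start:start + read_len]
        rev = revcomp(genome[start + ins - read_len:start + ins])
        if err_mask is not None:
            fwd = _apply_errors(fwd, err_mask[i, 0], shifts[i, 0])
            rev = _apply_errors(rev, err_mask[i, 1], shifts[i, 1])
        pid = f"pair_{i:07d}"
        if flip[i]:
            pairs.append(ReadPair(pid, rev, fwd, qual_str, qual_str))
            truth.read_map[pid + "/1"] = (start + ins - read_len, "reverse")
            truth.read_map[pid + "/2"] = (start, "forward")
        else:
            pairs.append(ReadPair(pid, fwd, rev, qual_str, qual_str))
            truth.read_map[pid + "/1"] = (start, "forward")
            truth.read_map[pid + "/2"] = (start + ins - read_len, "reverse")
    return pairs, truth


def _apply_errors(seq: str, mask: np.ndarray, shift: np.ndarray) -> str:
    if not mask.any():
        return seq
    chars = list(seq)
    for j in np.flatnonzero(mask):
        if chars[j] in _BASES:
            chars[j] = _BASES[(_BASES.index(chars[j]) + int(shift[j])) % 4]
    return "".join(chars)


# ---------------------------------------------------------------------------
# The natto-like scenario: one call that builds the full study condition.

def natto_like_scenario(seed: int = 0, ref_length: int = 200_000,
                        deletion_length: int = 20_000,
                        snp_rate: float = 0.002) -> dict:
    """Reference + derived genome pair emulating a natto/168-like strain pair.

    Two IS families (5 and 6 copies, 1.2/1.3 kbp), one operon-scale deletion,
    SNPs at ~0.2% and sparse 1-bp indels, per the scale of differences the
    pipeline is designed around.
    """
    reference = random_genome(ref_length, seed)
    is_a = random_is_element(1200, seed + 101)
    is_b = random_is_element(1300, seed + 202)
    deletion_length = min(deletion_length, ref_length // 10)
    del_pos = int(ref_length * 0.6)
    spec = MutationSpec(snp_rate=snp_rate, indel_rate=0.0002,
                        is_elements=((is_a, 5), (is_b, 6)),
                        deletions=((del_pos, deletion_length),),
                        seed=seed + 1)
    derived, truth = derive_genome(reference, spec)
    return {"reference": reference, "derived": derived, "truth": truth,
            "spec": spec, "is_elements": (is_a, is_b)}
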