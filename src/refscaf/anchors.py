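"""Anchor finding between scaffolds and a reference genome.

An anchor is a short, well-conserved *ungapped* match between a scaffold
interval and a reference interval, on either strand. Anchors are found by
spaced-seed hashing of the reference, seed lookup from both strands of the
query, ungapped extension of seed hits, and merging of overlapping co-linear
hits. A scaffold's representative anchor (used to place it) is its longest
anchor, with deterministic tie-breaking.

Indels split anchors: a gapped homology is reported as two (or more) anchors
on different diagonals. N bases never seed a hit and always count as
mismatches during extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqio import check_dna, revcomp

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class SeedPattern:
    """Spaced-seed pattern: '1' positions must match, '0' positions are free.

    `weight` is the number of match positions; sensitivity/specificity trade
    off through weight and span in the usual seeded-alignment way.
    """

    mask: str = "1" * 16

    def __post_init__(self):
        if set(self.mask) - {"0", "1"}:
            raise ValueError("seed mask must consist of '1' and '0' symbols")
        if self.weight < 8:
            raise ValueError("seed weight must be >= 8")
        if not (self.mask.startswith("1") and self.mask.endswith("1")):
            raise ValueError("seed mask must begin and end with a match position")

    @property
    def weight(self) -> int:
        return self.mask.count("1")

    @property
    def span(self) -> int:
        return len(self.mask)

    @property
    def offsets(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.mask) if c == "1")

    @property
    def contiguous(self) -> bool:
        return self.weight == self.span


DEFAULT_SEED = SeedPattern()


@dataclass(frozen=True, order=True)
class Anchor:
    """An ungapped match: scaffold [q_start, q_end) vs reference [r_start, r_end).

    Coordinates are 0-based half-open on the *forward* orientation of both
    sequences; for a reverse-strand anchor the reverse complement of the
    scaffold interval matches the reference interval.
    """

    scaffold_id: str = field(compare=False)
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    strand: str
    identity: float = field(compare=False)

    def __post_init__(self):
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.q_end - self.q_start != self.r_end - self.r_start:
            raise ValueError("anchor is gapped: query and reference spans differ")
        if min(self.q_start, self.r_start) < 0 or self.q_end <= self.q_start:
            raise ValueError("bad anchor coordinates")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity outside [0, 1]")

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


def seed_index(seq: str, pattern: SeedPattern = DEFAULT_SEED) -> dict[str, list[int]]:
    """Hash every seed-shaped word of `seq` to its positions (N words skipped).

    Build once and pass to find_anchors when anchoring many queries against
    the same reference."""
    index: dict[str, list[int]] = {}
    span = pattern.span
    if pattern.contiguous:
        for i in range(len(seq) - span + 1):
            key = seq[i:i + span]
            if "N" in key:
                continue
            index.setdefault(key, []).append(i)
    else:
        offs = pattern.offsets
        for i in range(len(seq) - span + 1):
            key = "".join(seq[i + o] for o in offs)
            if "N" in key:
                continue
            index.setdefault(key, []).append(i)
    return index


def _seed_key(seq: str, pos: int, pattern: SeedPattern) -> str:
    if pattern.contiguous:
        return seq[pos:pos + pattern.span]
    return "".join(seq[pos + o] for o in pattern.offsets)


def _extend(q: str, r: str, q_start: int, q_end: int, r_start: int,
            min_identity: float) -> tuple[int, int, int, int]:
    """Maximal ungapped extension of q[q_start:q_end] ~ r[r_start:...].

    Extends one base at a time in both directions while the identity of the
    extended interval stays >= min_identity; on return no single-base
    extension on either side keeps the identity above the threshold.
    Returns (q_start, q_end, r_start, matches).
    """
    r_end = r_start + (q_end - q_start)
    matches = sum(q[q_start + k] != "N" and q[q_start + k] == r[r_start + k]
                  for k in range(q_end - q_start))
    while True:
        moved = False
        # right
        while q_end < len(q) and r_end < len(r):
            hit = q[q_end] != "N" and q[q_end] == r[r_end]
            if (matches + hit) / (q_end - q_start + 1) < min_identity:
                break
            matches += hit
            q_end += 1
            r_end += 1
            moved = True
        # left
        while q_start > 0 and r_start > 0:
            hit = q[q_start - 1] != "N" and q[q_start - 1] == r[r_start - 1]
            if (matches + hit) / (q_end - q_start + 1) < min_identity:
                break
            matches += hit
            q_start -= 1
            r_start -= 1
            moved = True
        if not moved:
            return q_start, q_end, r_start, matches


def _count_matches(q: str, r: str, q_start: int, q_end: int, r_start: int) -> int:
    return sum(q[q_start + k] != "N" and q[q_start + k] == r[r_start + k]
               for k in range(q_end - q_start))


def _scan_strand(q: str, reference: str, index: dict[str, list[int]],
                 pattern: SeedPattern, min_len: int, min_identity: float,
                 ) -> list[tuple[int, int, int, int]]:
    """Seed, extend and merge on one (already oriented) query strand.

    Returns (q_start, q_end, r_start, matches) tuples in strand-local query
    coordinates, merged per diagonal.
    """
    span = pattern.span
    by_diag: dict[int, list[list[int]]] = {}
    for j in range(len(q) - span + 1):
        key = _seed_key(q, j, pattern)
        if "N" in key:
            continue
        for i in index.get(key, ()):
            d = i - j
            covered = by_diag.get(d)
            if covered and any(s <= j and j + span <= e for s, e, _ in covered):
                continue
            qs, qe, rs, m = _extend(q, reference, j, j + span, i, min_identity)
            by_diag.setdefault(d, []).append([qs, qe, m])
    hits = []
    for d, intervals in by_diag.items():
        intervals.sort()
        merged: list[list[int]] = []
        for qs, qe, m in intervals:
            if merged and qs <= merged[-1][1]:
                prev = merged[-1]
                if qe > prev[1]:
                    new_m = _count_matches(q, reference, prev[0], qe, prev[0] + d)
                    if new_m / (qe - prev[0]) >= min_identity:
                        prev[1], prev[2] = qe, new_m
                        continue
                    merged.append([qs, qe, m])
                # else fully contained: drop
            else:
                merged.append([qs, qe, m])
        for qs, qe, m in merged:
            # spaced-seed wildcards can leave an unextendable hit below the
            # identity floor; drop those here
            if qe - qs >= min_len and m / (qe - qs) >= min_identity:
                hits.append((qs, qe, qs + d, m))
    return hits


def find_anchors(query: str, reference: str, pattern: SeedPattern = DEFAULT_SEED,
                 min_len: int = 40, min_identity: float = 0.9,
                 scaffold_id: str = "query",
                 index: dict[str, list[int]] | None = None) -> list[Anchor]:
    """Find all maximal ungapped anchors between `query` and `reference`.

    Both strands of the query are searched. Every returned anchor has
    length >= min_len, identity >= min_identity, and cannot be lengthened on
    either side without its identity dropping below the threshold.
    Anchors are returned sorted by (r_start, q_start, strand). A prebuilt
    `seed_index(reference, pattern)` may be passed to amortise hashing.
    """
    query = check_dna(query, "query")
    reference = check_dna(reference, "reference")
    if pattern.weight > min_len:
        raise ValueError(f"seed weight {pattern.weight} exceeds min_len {min_len}")
    if not (0.0 < min_identity <= 1.0):
        raise ValueError("min_identity must be in (0, 1]")

    if index is None:
        index = seed_index(reference, pattern)
    anchors: set[Anchor] = set()
    qlen = len(query)
    for strand, q in ((FORWARD, query), (REVERSE, revcomp(query))):
        for qs, qe, rs, m in _scan_strand(q, reference, index, pattern,
                                          min_len, min_identity):
            if strand == FORWARD:
                fqs, fqe = qs, qe
            else:
                fqs, fqe = qlen - qe, qlen - qs
            anchors.add(Anchor(scaffold_id, fqs, fqe, rs, rs + (qe - qs),
                               strand, m / (qe - qs)))
    return sorted(anchors, key=lambda a: (a.r_start, a.q_start, a.strand))


def best_anchor(anchors: Sequence[Anchor]) -> Anchor:
    """The representative anchor: longest, ties by smaller r_start then q_start."""
    if not anchors:
        raise ValueError("best_anchor of an empty collection")
    ids = {a.scaffold_id for a in anchors}
    if len(ids) > 1:
        raise ValueError(f"anchors from multiple scaffolds: {sorted(ids)}")
    return min(anchors, key=lambda a: (-a.length, a.r_start, a.q_start))


def anchors_to_tsv(anchors: Iterable[Anchor]) -> str:
    lines = ["scaffold_id\tq_start\tq_end\tr_start\tr_end\tstrand\tlength\tidentity"]
    for a in anchors:
        lines.append(f"{a.scaffold_id}\t{a.q_start}\t{a.q_end}\t{a.r_start}\t"
                     f"{a.r_end}\t{a.strand}\t{a.length}\t{a.identity:.4f}")
    return "\n".join(lines) + "\n"
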