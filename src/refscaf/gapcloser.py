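"""Closing junctions between adjacent placed scaffolds.

Each junction between consecutive placements is resolved, in order of
preference, by (i) overlap merging — the longest suffix/prefix alignment
within the mismatch tolerance — or (ii) splicing the intervening interval of
the reference-guided draft, provided both scaffold ends locate uniquely on
the draft, in order, and every base between them is confident. Junctions
resolved neither way stay open and are emitted as N-runs sized by the
reference-coordinate distance between the flanking anchors (floored so gaps
survive downstream parsing).

Requiring full confidence of a spliced draft interval is deliberately
conservative: it prevents reference-specific sequence (e.g. an operon the
sequenced strain has lost) from being propagated into the assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np

from .anchors import DEFAULT_SEED, SeedPattern, find_anchors, seed_index
from .refguided import ReferenceGuidedDraft
from .scaffolder import Layout, Placement, Scaffold
from .seqio import revcomp

OVERLAP_MERGED = "overlap_merged"
DRAFT_FILLED = "draft_filled"
OPEN = "open"


@dataclass(frozen=True)
class CloseParams:
    min_overlap: int = 30
    max_mismatch_rate: float = 0.02
    min_gap_n: int = 100
    terminal_len: int = 1000    # scaffold terminus re-anchored onto the draft


@dataclass(frozen=True)
class Junction:
    left_id: str
    right_id: str
    status: str                     # overlap_merged | draft_filled | open
    overlap_len: int | None = None          # when overlap_merged
    insert_interval: tuple[int, int] | None = None   # draft coords, when draft_filled
    estimated_gap: int | None = None        # when open
    note: str = ""

    def __post_init__(self):
        present = {
            OVERLAP_MERGED: self.overlap_len is not None,
            DRAFT_FILLED: self.insert_interval is not None,
            OPEN: self.estimated_gap is not None,
        }
        if not present.pop(self.status, False) or any(present.values()):
            raise ValueError(f"junction detail does not match status {self.status}")


@dataclass(frozen=True)
class GapRecord:
    start: int              # on the final sequence, 0-based half-open N-run
    end: int
    estimated_size: int
    left_id: str
    right_id: str


@dataclass
class FinalAssembly:
    sequence: str
    gaps: list[GapRecord]
    junctions: list[Junction]
    agp: list[dict]
    components: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def census(self) -> dict[str, int]:
        c = {OVERLAP_MERGED: 0, DRAFT_FILLED: 0, OPEN: 0}
        for j in self.junctions:
            c[j.status] += 1
        return c


# ---------------------------------------------------------------------------
# Overlap merging

def _encode_for_overlap(seq: str, n_sentinel: int) -> "np.ndarray":
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = n_sentinel   # N never matches, not even another N
    return arr


def resolve_overlap(left: str, right: str, min_overlap: int = 30,
                    max_mismatch_rate: float = 0.02,
                    ) -> tuple[str, int] | None:
    """Longest suffix(left)/prefix(right) overlap within the mismatch budget.

    Returns (merged sequence, overlap length) or None. Overlap lengths are
    scanned from the longest possible downward; the first (longest) length
    whose mismatch rate is within tolerance wins. Mismatching positions take
    the base from whichever sequence the position is more interior to
    (sequence ends are the least reliable part of an assembly), ties to left.
    N counts as a mismatch.
    """
    max_ov = min(len(left), len(right))
    if max_ov < min_overlap:
        return None
    la = _encode_for_overlap(left[-max_ov:], 1)
    ra = _encode_for_overlap(right[:max_ov], 2)
    for ov in range(max_ov, min_overlap - 1, -1):
        budget = int(max_mismatch_rate * ov)
        mm = int(np.count_nonzero(la[max_ov - ov:] != ra[:ov]))
        if mm > budget:
            continue
        if mm == 0:
            return left + right[ov:], ov
        merged_ov = []
        lseg = left[len(left) - ov:]
        for i in range(ov):
            if lseg[i] == right[i]:
                merged_ov.append(lseg[i])
            else:
                merged_ov.append(lseg[i] if (ov - i) >= i else right[i])
        return left[:len(left) - ov] + "".join(merged_ov) + right[ov:], ov
    return None


# ---------------------------------------------------------------------------
# Draft filling

def _locate_terminus(term: str, draft: ReferenceGuidedDraft,
                     pattern: SeedPattern, min_len: int, min_identity: float,
                     unique_frac: float = 0.9,
                     index: dict | None = None) -> "tuple[int, int, int, int] | None":
    """Unique forward-strand location of a scaffold terminus on the draft.

    Returns the best anchor's (q_start, q_end, r_start, r_end) or None when
    the terminus does not anchor or anchors ambiguously (repeat copy).
    """
    anchors = [a for a in find_anchors(term, draft.sequence, pattern, min_len,
                                       min_identity, index=index)
               if a.strand == "forward"]
    if not anchors:
        return None
    best = max(anchors, key=lambda a: (a.length, -a.r_start, -a.q_start))
    diag = best.r_start - best.q_start
    for a in anchors:
        if a is best or a.length < unique_frac * best.length:
            continue
        if abs((a.r_start - a.q_start) - diag) > 10:
            return None    # ambiguous: a second near-best locus
    return best.q_start, best.q_end, best.r_start, best.r_end


def fill_from_draft(left: str, right: str, draft: ReferenceGuidedDraft,
                    pattern: SeedPattern = DEFAULT_SEED, min_len: int = 40,
                    min_identity: float = 0.9, terminal_len: int = 1000,
                    draft_index: dict | None = None,
                    ) -> tuple[str, tuple[int, int]] | None:
    """Sequence to splice between two oriented scaffolds, from the draft.

    Anchors the terminal `terminal_len` of `left` (its 3' end) and of `right`
    (its 5' end) onto the draft. Succeeds only when both ends locate uniquely,
    in order, and every intervening draft position is confident; returns
    (insert sequence, draft interval).
    """
    lterm = left[-terminal_len:]
    rterm = right[:terminal_len]
    lhit = _locate_terminus(lterm, draft, pattern, min_len, min_identity,
                            index=draft_index)
    rhit = _locate_terminus(rterm, draft, pattern, min_len, min_identity,
                            index=draft_index)
    if lhit is None or rhit is None:
        return None
    # project the actual scaffold ends onto draft coordinates
    lq_start, lq_end, lr_start, lr_end = lhit
    rq_start, rq_end, rr_start, rr_end = rhit
    left_end = lr_end + (len(lterm) - lq_end)
    right_start = rr_start - rq_start
    if left_end > right_start:
        return None   # ends out of order: overlap or rearrangement
    if left_end < 0 or right_start > len(draft.sequence):
        return None
    if not draft.confident_mask[left_end:right_start].all():
        return None
    insert = draft.sequence[left_end:right_start]
    if "N" in insert:
        return None
    return insert, (left_end, right_start)


# ---------------------------------------------------------------------------
# Layout closing

def oriented_sequence(placement: Placement, scaffolds: Mapping[str, str]) -> str:
    seq = scaffolds[placement.scaffold_id]
    return revcomp(seq) if placement.orientation == "reverse" else seq


def _ref_projection(placement: Placement, scaf_len: int) -> tuple[int, int]:
    """Reference interval the oriented scaffold should span, via its anchor."""
    a = placement.anchor
    if placement.orientation == "forward":
        oq_start, oq_end = a.q_start, a.q_end
    else:
        oq_start, oq_end = scaf_len - a.q_end, scaf_len - a.q_start
    return a.r_start - oq_start, a.r_end + (scaf_len - oq_end)


def close_layout(layout: Layout, scaffolds: Mapping[str, str],
                 draft: ReferenceGuidedDraft | None = None,
                 params: CloseParams = CloseParams(),
                 pattern: SeedPattern = DEFAULT_SEED, min_len: int = 40,
                 min_identity: float = 0.9, object_id: str = "final",
                 ) -> FinalAssembly:
    """Resolve every junction of the layout and emit the final assembly.

    Per junction: overlap merge first, then draft splice, else an open N-gap
    sized max(reference-distance estimate, min_gap_n). The junction census
    always sums to (placed scaffolds - 1).
    """
    if not layout.placements:
        raise ValueError("cannot close an empty layout")
    if draft is not None and draft.reference_id != layout.reference_id:
        raise ValueError(
            f"draft was built against {draft.reference_id!r} but the layout "
            f"is on {layout.reference_id!r}")

    draft_index = (seed_index(draft.sequence, pattern)
                   if draft is not None else None)
    junctions: list[Junction] = []
    gaps: list[GapRecord] = []
    components: list[tuple[str, int, int]] = []
    agp: list[dict] = []

    first = layout.placements[0]
    assembled = oriented_sequence(first, scaffolds)
    components.append((first.scaffold_id, 0, len(assembled)))
    agp.append(_component_row(first, 0, len(assembled), 0))

    for prev, cur in zip(layout.placements, layout.placements[1:]):
        right = oriented_sequence(cur, scaffolds)
        merged = resolve_overlap(assembled, right, params.min_overlap,
                                 params.max_mismatch_rate)
        if merged is not None:
            new_assembled, ov = merged
            junctions.append(Junction(prev.scaffold_id, cur.scaffold_id,
                                      OVERLAP_MERGED, overlap_len=ov))
            start = len(assembled) - ov
            assembled = new_assembled
            components.append((cur.scaffold_id, start, len(assembled)))
            agp.append(_component_row(cur, start, len(assembled), ov))
            continue
        filled = None
        if draft is not None:
            filled = fill_from_draft(assembled, right, draft, pattern, min_len,
                                     min_identity, params.terminal_len,
                                     draft_index=draft_index)
        if filled is not None:
            insert, interval = filled
            junctions.append(Junction(prev.scaffold_id, cur.scaffold_id,
                                      DRAFT_FILLED, insert_interval=interval))
            if insert:
                components.append((f"draft_{interval[0]}_{interval[1]}",
                                   len(assembled), len(assembled) + len(insert)))
                agp.append({"obj_start": len(assembled),
                            "obj_end": len(assembled) + len(insert),
                            "component_id": f"draft_{interval[0]}_{interval[1]}",
                            "comp_start": 0, "comp_end": len(insert),
                            "orientation": "+"})
            assembled += insert
            start = len(assembled)
            assembled += right
            components.append((cur.scaffold_id, start, len(assembled)))
            agp.append(_component_row(cur, start, len(assembled), 0))
            continue
        # open gap
        est = _estimate_gap(prev, cur, scaffolds)
        n_len = max(est, params.min_gap_n)
        junctions.append(Junction(prev.scaffold_id, cur.scaffold_id, OPEN,
                                  estimated_gap=est))
        gap_start = len(assembled)
        assembled += "N" * n_len
        gaps.append(GapRecord(gap_start, len(assembled), n_len,
                              prev.scaffold_id, cur.scaffold_id))
        agp.append({"obj_start": gap_start, "obj_end": len(assembled),
                    "gap_length": n_len, "gap_type": "scaffold",
                    "linkage": "yes", "evidence": "align_genus"})
        start = len(assembled)
        assembled += right
        components.append((cur.scaffold_id, start, len(assembled)))
        agp.append(_component_row(cur, start, len(assembled), 0))

    assert len(junctions) == len(layout.placements) - 1
    return FinalAssembly(assembled, gaps, junctions, agp, components)


def _component_row(p: Placement, obj_start: int, obj_end: int,
                   trimmed: int) -> dict:
    n = obj_end - obj_start + trimmed
    return {"obj_start": obj_start, "obj_end": obj_end,
            "component_id": p.scaffold_id,
            "comp_start": trimmed, "comp_end": n,
            "orientation": "+" if p.orientation == "forward" else "-"}


def _estimate_gap(prev: Placement, cur: Placement,
                  scaffolds: Mapping[str, str]) -> int:
    _, left_end = _ref_projection(prev, len(scaffolds[prev.scaffold_id]))
    right_start, _ = _ref_projection(cur, len(scaffolds[cur.scaffold_id]))
    return max(0, right_start - left_end)


# ---------------------------------------------------------------------------
# Post-closing screens

def screen_contained(small_scaffolds: Sequence[Scaffold], final: FinalAssembly,
                     max_mismatch_rate: float = 0.02) -> list[str]:
    """Ids of scaffolds found end-to-end inside the final sequence.

    A scaffold is contained iff it (or its reverse complement) aligns within
    the final sequence with at most max_mismatch_rate * length edits.
    """
    contained = []
    target = final.sequence
    for scaf in small_scaffolds:
        k = int(max_mismatch_rate * len(scaf))
        for seq in (scaf.sequence, revcomp(scaf.sequence)):
            res = edlib.align(seq, target, mode="HW", task="distance", k=k)
            if res["editDistance"] != -1:
                contained.append(scaf.id)
                break
    return contained


def place_unplaced_into_gaps(unplaced: Sequence[Scaffold], final: FinalAssembly,
                             params: CloseParams = CloseParams(),
                             flank_len: int = 500,
                             ) -> tuple[list[dict], list[str]]:
    """Suggest unplaced scaffolds for open gaps by flank overlap (report only).

    A scaffold is suggested for a gap iff one of its ends overlaps a gap flank
    per resolve_overlap, in either orientation. Scaffolds sharing no seed-size
    word with the final sequence at all (plasmid-like content) are returned
    separately and never suggested. The assembly is not modified.
    """
    k = 16
    words = {final.sequence[i:i + k] for i in range(len(final.sequence) - k + 1)}
    suggestions: list[dict] = []
    no_anchor: list[str] = []
    for scaf in unplaced:
        seq = scaf.sequence
        if not any(seq[i:i + k] in words for i in range(0, len(seq) - k + 1, k)):
            no_anchor.append(scaf.id)
            continue
        for gi, gap in enumerate(final.gaps):
            lflank = final.sequence[max(0, gap.start - flank_len):gap.start]
            rflank = final.sequence[gap.end:gap.end + flank_len]
            for orient, s in (("forward", seq), ("reverse", revcomp(seq))):
                hit = resolve_overlap(lflank, s, params.min_overlap,
                                      params.max_mismatch_rate)
                if hit is not None:
                    suggestions.append({"gap_index": gi, "scaffold_id": scaf.id,
                                        "orientation": orient, "side": "left",
                                        "overlap_len": hit[1]})
                    continue
                hit = resolve_overlap(s, rflank, params.min_overlap,
                                      params.max_mismatch_rate)
                if hit is not None:
                    suggestions.append({"gap_index": gi, "scaffold_id": scaf.id,
                                        "orientation": orient, "side": "right",
                                        "overlap_len": hit[1]})
    return suggestions, no_anchor
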