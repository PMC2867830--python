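"""Ordering and orienting de novo scaffolds along a close reference.

Scaffolds longer than the length floor are anchored to the reference; each
anchored scaffold is placed at the location of its *longest* anchor, oriented
by that anchor's strand, and the placements are sorted by reference position.
Scaffolds with no anchor (strain-specific content: IS elements, phages,
plasmids) are reported unplaced. Scaffolds whose secondary anchors disagree
with the representative one (other strand, or a distant locus) are flagged as
misassembly/chimera candidates but never split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .anchors import (DEFAULT_SEED, Anchor, SeedPattern, best_anchor,
                      find_anchors, seed_index)
from .seqio import check_dna


@dataclass(frozen=True)
class Scaffold:
    id: str
    sequence: str

    def __post_init__(self):
        check_dna(self.sequence, f"scaffold {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Placement:
    scaffold_id: str
    orientation: str          # equals the representative anchor's strand
    anchor: Anchor            # the longest anchor
    rank: int = -1

    @property
    def ref_position(self) -> int:
        return self.anchor.r_start


@dataclass
class Layout:
    """Ordered, oriented arrangement of scaffolds along one reference."""

    reference_id: str
    placements: list[Placement] = field(default_factory=list)
    unplaced: list[str] = field(default_factory=list)
    below_min: list[str] = field(default_factory=list)
    conflict_warnings: dict[str, str] = field(default_factory=dict)

    @property
    def placed_ids(self) -> list[str]:
        return [p.scaffold_id for p in self.placements]


def filter_by_length(scaffolds: Sequence[Scaffold], min_len: int = 1000,
                     ) -> tuple[list[Scaffold], list[Scaffold]]:
    """Partition scaffolds into those strictly longer than min_len and the rest."""
    kept = [s for s in scaffolds if len(s) > min_len]
    below = [s for s in scaffolds if len(s) <= min_len]
    return kept, below


def place_scaffolds(scaffolds: Sequence[Scaffold], reference: str,
                    pattern: SeedPattern = DEFAULT_SEED, min_len: int = 40,
                    min_identity: float = 0.9, reference_id: str = "reference",
                    ) -> Layout:
    """Anchor, orient and order scaffolds along the reference.

    Each scaffold is placed by its longest anchor; placements are sorted by
    reference position with ties broken by scaffold id. Scaffolds without
    anchors go to `unplaced`.
    """
    reference = check_dna(reference, "reference")
    ids = [s.id for s in scaffolds]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate scaffold ids: {dupes}")

    layout = Layout(reference_id=reference_id)
    index = seed_index(reference, pattern)
    placements: list[Placement] = []
    for scaf in scaffolds:
        anchors = find_anchors(scaf.sequence, reference, pattern, min_len,
                               min_identity, scaffold_id=scaf.id, index=index)
        if not anchors:
            layout.unplaced.append(scaf.id)
            continue
        rep = best_anchor(anchors)
        conflict = _conflict_note(rep, anchors, len(scaf))
        if conflict:
            layout.conflict_warnings[scaf.id] = conflict
        placements.append(Placement(scaf.id, rep.strand, rep))
    placements.sort(key=lambda p: (p.ref_position, p.scaffold_id))
    layout.placements = [
        Placement(p.scaffold_id, p.orientation, p.anchor, rank=i)
        for i, p in enumerate(placements)]
    layout.unplaced.sort()
    return layout


def _conflict_note(rep: Anchor, anchors: Sequence[Anchor], scaf_len: int,
                   min_frac: float = 0.25) -> str | None:
    """Flag substantial secondary anchors disagreeing with the representative.

    Disagreement = opposite strand, or a reference locus farther from the
    representative than the scaffold is long (an IS-copy jump or chimera).
    """
    floor = max(rep.length * min_frac, 100)
    for a in anchors:
        if a == rep or a.length < floor:
            continue
        if a.strand != rep.strand:
            return (f"secondary anchor on {a.strand} strand at r={a.r_start} "
                    f"disagrees with representative ({rep.strand} at {rep.r_start})")
        if abs(a.r_start - rep.r_start) > 2 * scaf_len:
            return (f"secondary anchor at distant locus r={a.r_start} "
                    f"(representative at {rep.r_start})")
    return None


def layout_to_agp_rows(layout: Layout, scaffolds: Mapping[str, str]) -> list[dict]:
    """Render a layout as AGP component rows with inter-scaffold gap rows of
    unknown size (pre-gap-closing view)."""
    rows: list[dict] = []
    pos = 0
    for i, p in enumerate(layout.placements):
        if i:
            rows.append({"obj_start": pos, "obj_end": pos + 100, "gap_length": 100,
                         "unknown": True, "gap_type": "scaffold",
                         "evidence": "align_genus"})
            pos += 100
        n = len(scaffolds[p.scaffold_id])
        rows.append({"obj_start": pos, "obj_end": pos + n,
                     "component_id": p.scaffold_id, "comp_start": 0, "comp_end": n,
                     "orientation": "+" if p.orientation == "forward" else "-"})
        pos += n
    return rows
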