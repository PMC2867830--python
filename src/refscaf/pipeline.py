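"""One-call pipeline: draft -> place -> close -> digest, with file outputs.

Mirrors the four-stage finishing recipe the package implements: (i) map reads
onto the reference and call the reference-guided draft, (ii) order and orient
de novo scaffolds by their anchors, (iii) close junctions by overlap merging
and draft splicing, (iv) emit the remaining gaps (with primer flanks for
bench follow-up) plus validation reports (restriction map, mapping stats).

Stage counts are logged so a run can be compared qualitatively against the
narrative of a real finishing project (scaffolds placed/unplaced, junction
census, gaps left open).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import gapcloser, refguided, restmap, scaffolder, seqio
from .anchors import SeedPattern, anchors_to_tsv

log = logging.getLogger("refscaf")


@dataclass
class PipelineConfig:
    reference: str = ""
    scaffolds: str = ""
    reads1: str | None = None
    reads2: str | None = None
    sam: str | None = None
    outdir: str = "refscaf_out"
    seed: int = 0
    threads: int = 1            # accepted for CLI parity; results never depend on it
    min_scaffold_len: int = 1000
    seed_mask: str = "1" * 16
    anchor_min_len: int = 40
    anchor_min_identity: float = 0.9
    quality_cutoff: int = 40
    min_depth: int = 1
    mapper_k: int = 18
    min_overlap: int = 30
    max_mismatch_rate: float = 0.02
    min_gap_n: int = 100
    enzyme: str = "SfiI"
    topology: str = "linear"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.reference:
            raise ValueError("config requires a reference FASTA path")
        if not Path(self.reference).exists():
            raise FileNotFoundError(self.reference)
        if not self.scaffolds:
            raise ValueError("config requires a scaffolds FASTA path")
        if not Path(self.scaffolds).exists():
            raise FileNotFoundError(self.scaffolds)
        for p in (self.reads1, self.reads2, self.sam):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.enzyme not in restmap.ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}; "
                             f"known: {sorted(restmap.ENZYMES)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write every intermediate under config.outdir."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    pattern = SeedPattern(config.seed_mask)

    ref_records = seqio.read_fasta(config.reference)
    ref_id, reference = next(iter(ref_records.items()))
    scaffold_seqs = seqio.read_fasta(config.scaffolds)
    scaffolds = [scaffolder.Scaffold(i, s) for i, s in scaffold_seqs.items()]
    log.info("loaded %d scaffolds, reference %s (%d bp)",
             len(scaffolds), ref_id, len(reference))

    # stage (i): reference-guided draft
    draft = None
    report = None
    if config.reads1 and config.reads2:
        pairs = [refguided.ReadPair(i, s1, s2,
                                    "".join(chr(q + 33) for q in q1),
                                    "".join(chr(q + 33) for q in q2))
                 for i, s1, q1, s2, q2 in
                 seqio.read_fastq_pairs(config.reads1, config.reads2)]
        alignments = refguided.map_reads_naive(pairs, reference, k=config.mapper_k)
        (out / "alignments.sam").write_text(
            refguided.alignments_to_sam(alignments, ref_id, len(reference)))
    elif config.sam:
        alignments = refguided.parse_sam(config.sam)
    else:
        alignments = None
    if alignments is not None:
        params = refguided.ConsensusParams(config.quality_cutoff, config.min_depth)
        draft = refguided.build_draft(alignments, reference, params,
                                      reference_id=ref_id)
        report = refguided.mapping_report(alignments, reference, draft)
        seqio.write_fasta(out / "draft.fa", {f"{ref_id}_draft": draft.sequence})
        _write_nonconfident_bed(out / "draft_nonconfident.bed", draft, ref_id)
        (out / "mapping_report.tsv").write_text(
            "mapped_fraction\tmean_fold_coverage\tfrac_q40\tfrac_q30\n"
            f"{report.mapped_fraction:.4f}\t{report.mean_fold_coverage:.2f}\t"
            f"{report.frac_q40:.4f}\t{report.frac_q30:.4f}\n")
        log.info("draft: %.1f%% reads mapped, %.0f-fold coverage, "
                 "%.1f%% of covered bases confident at Q%d",
                 100 * report.mapped_fraction, report.mean_fold_coverage,
                 100 * report.frac_q40, config.quality_cutoff)

    # stage (ii): length filter, anchor, order + orient
    kept, below = scaffolder.filter_by_length(scaffolds, config.min_scaffold_len)
    layout = scaffolder.place_scaffolds(kept, reference, pattern,
                                        config.anchor_min_len,
                                        config.anchor_min_identity,
                                        reference_id=ref_id)
    log.info("placed %d / %d scaffolds >%d bp (%d unplaced, %d below length)",
             len(layout.placements), len(kept), config.min_scaffold_len,
             len(layout.unplaced), len(below))
    for sid, note in layout.conflict_warnings.items():
        log.warning("scaffold %s: %s", sid, note)
    all_anchors = [p.anchor for p in layout.placements]
    (out / "anchors.tsv").write_text(anchors_to_tsv(all_anchors))
    (out / "layout.agp").write_text(seqio.agp_rows_to_text(
        "layout", scaffolder.layout_to_agp_rows(layout, scaffold_seqs)))
    (out / "unplaced.tsv").write_text(
        "".join(f"{sid}\n" for sid in layout.unplaced))

    # stage (iii)+(iv): close junctions, emit final assembly and open gaps
    close_params = gapcloser.CloseParams(config.min_overlap,
                                         config.max_mismatch_rate,
                                         config.min_gap_n)
    final = gapcloser.close_layout(layout, scaffold_seqs, draft, close_params,
                                   pattern, config.anchor_min_len,
                                   config.anchor_min_identity)
    census = final.census
    log.info("junctions: %d overlap-merged, %d draft-filled, %d open",
             census["overlap_merged"], census["draft_filled"], census["open"])
    seqio.write_fasta(out / "final.fa", {"final": final.sequence})
    (out / "final.agp").write_text(seqio.agp_rows_to_text("final", final.agp))
    seqio.write_bed(out / "gaps.bed",
                    [("final", g.start, g.end, f"{g.left_id}|{g.right_id}")
                     for g in final.gaps])
    (out / "junctions.tsv").write_text(_junctions_tsv(final))
    _write_primer_flanks(out / "gap_flanks.fa", final)

    contained = gapcloser.screen_contained(below, final, config.max_mismatch_rate)
    unplaced_scafs = [s for s in kept if s.id in set(layout.unplaced)]
    suggestions, no_anchor = gapcloser.place_unplaced_into_gaps(
        unplaced_scafs, final, close_params)
    log.info("%d / %d short scaffolds contained in the final sequence; "
             "%d gap suggestions for unplaced scaffolds; %d plasmid-like",
             len(contained), len(below), len(suggestions), len(no_anchor))

    frags = restmap.digest(final.sequence, restmap.ENZYMES[config.enzyme],
                           config.topology)
    (out / "fragments.tsv").write_text(restmap.fragments_to_tsv(frags))

    return {"layout": layout, "draft": draft, "final": final,
            "mapping_report": report, "fragments": frags,
            "contained": contained, "suggestions": suggestions,
            "plasmid_like": no_anchor}


def _write_nonconfident_bed(path: Path, draft, ref_id: str) -> None:
    intervals = []
    start = None
    mask = draft.confident_mask
    for i, ok in enumerate(mask):
        if not ok and start is None:
            start = i
        elif ok and start is not None:
            intervals.append((ref_id, start, i, "low_confidence"))
            start = None
    if start is not None:
        intervals.append((ref_id, start, len(mask), "low_confidence"))
    seqio.write_bed(path, intervals)


def _junctions_tsv(final) -> str:
    lines = ["left_id\tright_id\tstatus\tdetail"]
    for j in final.junctions:
        if j.status == gapcloser.OVERLAP_MERGED:
            detail = f"overlap={j.overlap_len}"
        elif j.status == gapcloser.DRAFT_FILLED:
            detail = f"draft_interval={j.insert_interval[0]}-{j.insert_interval[1]}"
        else:
            detail = f"estimated_gap={j.estimated_gap}"
        lines.append(f"{j.left_id}\t{j.right_id}\t{j.status}\t{detail}")
    return "\n".join(lines) + "\n"


def _write_primer_flanks(path: Path, final, flank: int = 500) -> None:
    records = {}
    for i, g in enumerate(final.gaps):
        left = final.sequence[max(0, g.start - flank):g.start]
        right = final.sequence[g.end:g.end + flank]
        records[f"gap{i}_left_{g.left_id}"] = left or "N"
        records[f"gap{i}_right_{g.right_id}"] = right or "N"
    if records:
        seqio.write_fasta(path, records)
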