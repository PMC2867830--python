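# refscaf

Reference-guided finishing of de novo bacterial genome assemblies from very
short reads.

## The problem

De novo assembly of a bacterial genome from very short reads (~36 bp
paired-end) unavoidably fragments at repeats — insertion sequences (IS),
rRNA/tRNA clusters, prophages — leaving dozens to hundreds of scaffolds. When
a closely related finished genome exists (e.g. a laboratory strain a few SNPs
per kilobase away from the strain of interest), the two assembly modes
complement each other: reference-guided consensus covers everything shared
with the reference but is blind to strain-specific sequence, while de novo
scaffolds capture strain-specific insertions but cannot be ordered on their
own. `refscaf` combines them:

1. **draft** — map reads onto the reference and call a per-base consensus
   (the *reference-guided draft*) with a Phred-scale confidence per position;
   positions with consensus quality ≥ Q40 form the confident mask.
2. **place** — find *anchors* (maximal ungapped matches found by spaced-seed
   hashing and extension) between each scaffold > 1 kbp and the reference;
   order and orient each scaffold by its longest anchor.
3. **close** — resolve each junction between adjacent scaffolds: merge a
   suffix/prefix overlap if one exists within the mismatch tolerance,
   otherwise splice the intervening draft interval if both scaffold ends
   locate uniquely on the draft and every base between them is confident,
   otherwise leave an N-gap sized by the reference-coordinate distance (with
   ±500 bp flanks exported for PCR primer design).
4. **validate** — in-silico restriction digest compared against a physical
   map at gel tolerance (±3%), in-silico PCR product-size prediction, and
   held-out read remapping.

A seeded synthetic generator (`refscaf simulate`) produces reference/derived
genome pairs with multi-copy IS repeats, an operon-scale deletion, SNPs and
1-bp indels, scaffolds broken preferentially at repeat copies, and 36 bp
paired-end reads with ~163 bp inserts — together with truth tables, so every
stage's recovery is measurable exactly.

## The core quantities

- An **anchor** between scaffold *q* and reference *r* is a maximal ungapped
  pair of intervals with identity ≥ 0.9 (default) and length ≥ 40; a scaffold
  is placed at its longest anchor's reference position, oriented by that
  anchor's strand.
- The consensus at a reference position with observations
  {(bᵢ, qᵢ)} calls b* = argmax_b Σ_{bᵢ=b} qᵢ with quality
  Q = Σ_agree qᵢ − Σ_disagree qᵢ, floored at 0, capped at 93; ties and empty
  columns call N. A position is *confident* iff Q ≥ 40 and depth ≥ 1.
- An overlap merge joins left/right scaffolds at the longest suffix/prefix
  alignment with mismatch rate ≤ 0.02 and length ≥ 30.
- A restriction fragment pair (a, b) matches iff |a − b| ≤ 0.03·max(a, b).

## Worked example

```
$ refscaf simulate --length 100000 --seed 11 --fold-coverage 20 --outdir sim
scenario (seed 11) -> sim: 32 scaffolds, 28834 read pairs

$ cat > cfg.yaml <<EOF
reference: sim/reference.fa
scaffolds: sim/scaffolds.fa
reads1: sim/reads_1.fq
reads2: sim/reads_2.fq
outdir: out
EOF

$ refscaf run --config cfg.yaml
INFO refscaf: loaded 32 scaffolds, reference reference (100000 bp)
INFO refscaf: draft: 85.5% reads mapped, 18-fold coverage, 99.9% of covered bases confident at Q40
INFO refscaf: placed 27 / 27 scaffolds >1000 bp (0 unplaced, 5 below length)
WARNING refscaf: scaffold scaffold_22: secondary anchor at distant locus r=58191 (representative at 69999)
INFO refscaf: junctions: 22 overlap-merged, 2 draft-filled, 2 open
INFO refscaf: 3 / 5 short scaffolds contained in the final sequence; 0 gap suggestions for unplaced scaffolds; 0 plasmid-like
final assembly: 102209 bp; junctions {'overlap_merged': 22, 'draft_filled': 2, 'open': 2}
```

Reading the output: 85.5% of reads map to the reference — the rest come from
strain-specific IS copies and so cannot map, exactly the sequence the de novo
scaffolds contribute. All 27 scaffolds above the 1 kbp floor anchor and
place; the chimera warning flags a scaffold whose secondary anchor points at
a distant locus (an IS-copy jump — a misassembly candidate, flagged but never
split). Of the 26 junctions, 22 close by overlap merging, 2 by splicing
confident draft sequence, and 2 stay open as N-gaps whose ±500 bp flanks are
written to `out/gap_flanks.fa` for primer design. The final assembly is
longer than the reference because it carries the derived strain's 11 IS
copies. `out/` also holds the SAM alignments, draft FASTA + low-confidence
BED, AGP 2.1 layouts, junction TSV and the SfiI fragment table.

Individual stages are available as `refscaf anchors / draft / place / close /
digest / pcr`.

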