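# Methods

This note documents the models and procedures implemented in `refscaf`, the
parameters that matter, the numerical conventions, and what the synthetic
benchmarks do and do not demonstrate.

## Anchors

An anchor is an ungapped, well-conserved match between a scaffold interval
and a reference interval, on either strand. Anchors are found by hashing
every seed-shaped word of the reference (default: contiguous weight-16 seed;
arbitrary spaced-seed masks of weight ≥ 8 are supported), looking seeds up
from both strands of the query, extending each hit one base at a time in both
directions for as long as the interval identity stays at or above the floor,
and merging overlapping co-linear hits per diagonal. Extension is maximal in
the sense that no single-base extension on either side keeps the identity
above the floor. With `min_identity = 1.0` the anchor set provably equals the
set of maximal exact matches (any exact match of length ≥ seed weight
contains a seed word), which is what the brute-force oracle tests exploit.

Defaults: contiguous weight-16 seed, `min_len = 40`, `min_identity = 0.9`.
These are chosen so that scaffolds assembled from 36 bp reads of a strain a
few SNPs per kilobase away from the reference (one mismatch per ~500 bp at
0.2% divergence) anchor reliably: an exact 16-mer occurs between consecutive
SNPs with high probability, and 40 bp at ≥ 90% identity tolerates the
divergence while rejecting chance matches (random expectation ≪ 1 per genome
at these thresholds). Indels deliberately split anchors — each collinear
ungapped piece is reported separately — which keeps anchors checkable against
a brute-force oracle and makes diagonal jumps visible. N never seeds and
always counts as a mismatch.

The representative anchor of a scaffold is its longest, with ties broken by
smaller reference start, then smaller query start — a total order, so
placement is deterministic.

## Reference-guided draft

Reads are placed by exact k-mer seeding (default k = 18, the two read halves
of a 36 bp read, so any single-error read still seeds) followed by ungapped
scoring of all candidate positions on both strands; a read goes to its
best-scoring position if at least 90% of its bases match, is flagged
multi-mapping (MAPQ 0) when several positions tie, and is unmapped otherwise.
Multi-mapping reads are excluded from the consensus so that IS repeat copies
cannot vote on each other's columns. The mapper exists to make the pipeline
self-contained; any SAM from any mapper is accepted equivalently.

The consensus is an additive Phred vote: at each reference position the
called base maximises the summed qualities of agreeing observations, and its
quality is the agreeing sum minus the disagreeing sum (gap and N observations
count against), floored at 0 and capped at 93. Empty columns and ties call N
at quality 0. This is deliberately *not* a Bayesian genotype model: it is
monotone (more agreement never lowers the call), transparent (every value can
be recomputed by hand), and sufficient for a haploid consensus at ≥ 20-fold
coverage. A position is confident iff its quality reaches the cutoff
(default Q40) and its depth reaches `min_depth` (default 1 — at constant
read quality 35 the Q40 cutoff already implies two agreeing reads, so the
depth knob is left permissive).

The draft is coordinate-locked to the reference: insertions relative to the
reference are counted but never placed. Novel sequence is recovered by the de
novo scaffolds instead — exactly the division of labour the pipeline relies
on. The mapping report gives the mapped-read fraction, fold coverage
(Σ aligned bases / reference length), and the fraction of covered positions
with consensus quality ≥ 40 / ≥ 30.

## Placement

Scaffolds of length > 1000 bp (strict) are anchored; each anchored scaffold
is placed at its representative anchor's reference position and oriented by
its strand; placements sort by reference position with ties broken by
scaffold id. Scaffolds with no anchor are reported unplaced — in a real
strain pair these are IS elements, phages and plasmids. A scaffold whose
secondary anchors disagree with the representative (opposite strand, or a
locus farther away than twice the scaffold length) is flagged as a chimera /
misassembly candidate but never split: the longest anchor alone decides.

## Junction closing

Junctions between consecutive placements are resolved in a fixed order of
preference:

1. **Overlap merge.** The longest suffix(left)/prefix(right) alignment with
   length ≥ `min_overlap` (30) and mismatch rate ≤ `max_mismatch_rate`
   (0.02). Lengths are scanned longest-first, so the reported overlap is the
   longest admissible one. At mismatching positions the merged base is taken
   from whichever scaffold the position is more interior to, with exact
   midpoint ties going to the left scaffold — scaffold ends are the least
   reliable part of a short-read assembly, so the base farther from its own
   scaffold end is preferred.
2. **Draft splice.** The terminal 1 kbp of each flanking scaffold is
   re-anchored onto the draft. The splice happens only when both termini
   locate uniquely (no second near-best locus — a repeat-copy terminus is
   ambiguous and refused), in order, and *every* intervening draft position
   is confident. Requiring full confidence is conservative by design: a
   region the reference has but the sequenced strain lacks (an operon-scale
   deletion) shows a coverage/quality hole, and splicing across it would
   propagate reference-specific sequence into the assembly.
3. **Open gap.** An N-run sized by the reference-coordinate distance between
   the projected scaffold ends, floored at `min_gap_n` (100) so gaps survive
   round-trips through downstream formats. ±500 bp flanks around each open
   gap are exported for primer design; gap closure by actual PCR/Sanger is
   outside the package's scope.

The junction census (merged + spliced + open = placed − 1) is asserted
structurally. Scaffolds below the length floor are screened for containment
in the final sequence by edlib infix alignment at the same mismatch
tolerance, either strand. Unplaced scaffolds are *suggested* for open gaps
when one of their ends overlaps a gap flank; suggestions never mutate the
assembly, and scaffolds sharing no 16-mer with the final sequence are listed
separately as plasmid-like.

AGP output note: when two components merge with mismatches inside the
overlap, the object sequence in the overlap region is the resolved mix, so
component rows there are approximate provenance; with exact overlaps (the
common case) AGP rows reproduce the object sequence exactly.

## Restriction map and in-silico PCR

Digestion cuts at every IUPAC match of the recognition motif, both strands
collapsed (a single scan for palindromes such as SfiI `GGCCNNNNNGGCC`).
Cuts are placed at the motif start: at gel tolerance the intra-motif cut
offset is irrelevant and only fragment sizes are compared. One consequence,
verified in the tests: on linear templates the two end fragments trade
motif-length bp under reverse complementation, while circular digests and
interior fragments are exactly strand-invariant. Fragment-map comparison is
order-preserving (both maps are position-anchored) with relative tolerance
0.03 per pair — the sizing error of pulsed-field gels.

In-silico PCR reports a product for every forward-primer site i and
reverse-primer site ending at e (the reverse complement of the reverse
primer on the forward strand), with i < e, product length e − i ≤
`max_product` and ≥ the combined primer length, wrapping the origin on
circular templates. Default matching is exact; with a mismatch budget the
3'-terminal base must still match exactly, since a 3' mismatch abolishes
extension in a real reaction. Sizes are reported in bp and rounded to
0.01 kb.

## Synthetic data

The generator emulates the structure of a natto/168-like strain pair, which
is also the study condition of the validation experiments:

- reference: random sequence at 43.5% GC (typical *Bacillus*), default
  200 kbp for round-trip experiments and 100 kbp for consensus and pipeline
  reports — the repeat structure and read geometry of a small bacterial
  finishing project at desk scale, not its full ~4 Mbp size;
- derived genome: two IS families (1.2/1.3 kbp, 5 and 6 copies — the
  IS4Bsu1/IS256 copy numbers of the motivating strain pair), one
  operon-scale deletion (20 kbp, capped at 10% of small references), SNPs at
  0.2% and 1-bp indels at 0.02% by default; the edit list replays to the
  derived genome byte-exactly and provides an exact reference↔derived
  coordinate map;
- scaffolds: breakpoints placed inside each repeat copy (short-read
  assemblies terminate at repeats) plus uniform random breaks, with either
  true overlaps or true gaps between consecutive pieces and a configurable
  reverse-complemented fraction; pieces are shuffled and the truth layout
  retained;
- reads: 36 bp paired-end, truncated-normal insert of mean 163 bp (sd 15),
  pair count ⌈coverage·L/(2·36)⌉, i.i.d. substitution errors, constant
  Phred-35 quality strings.

Constant base qualities keep the consensus arithmetic transparent but do not
reproduce real instrument error profiles (3'-degrading quality, correlated
errors); the generator also omits indel sequencing errors, GC-coverage bias
and chimeric pairs. Passing the recovery tests therefore demonstrates the
*logic* of anchoring, ordering and gap closing under the dominant real-data
failure modes (repeats, divergence, strain-specific sequence), not
robustness to instrument artefacts.

## Numerical conventions and degenerate inputs

All internal coordinates are 0-based half-open; AGP rows are converted to
1-based inclusive only on output. All randomness flows through
`numpy.random.default_rng` on explicit seeds; identical inputs and seeds give
byte-identical outputs, independent of thread count (the `--threads` flag is
interface parity only). Empty sequences are input errors; an empty pileup
column calls (N, 0); a no-site digest returns one full-length fragment; a
layout with a single scaffold closes to that scaffold unchanged; closing an
empty layout is an error.

## Validation experiments

`refscaf.validation` packages the seeded experiments used by the test suite
and `scripts/acceptance.py`: overlap round trip (200 kbp, ~30 pieces, 50 bp
overlaps → exact reconstruction), draft-splice round trip (100–300 bp true
gaps, error-free 30× reads → exact reconstruction), placement recovery
(50 pieces of a 1%-SNP derived genome, 30% reverse-complemented → ≥95%
ordered and oriented), consensus accuracy (error-free limit exact; at 1%
read error the confident-position error rate < 10⁻⁴), and the full pipeline
on the natto-like pair (mapped fraction, Q40 fraction, junction census,
held-out read remapping). The operon-deletion PCR check designs primers in
polymorphism-free flanks of the deleted interval and compares the in-silico
product against the truth table's coordinate-mapped prediction. The analogous
check on the real deposited genome pair is available when those two genomes
are downloaded (`data/genomes/README.md`); it is the only check that cannot
run without network access.

## Known limitations

Single-replicon references only (plasmids are handled as separate
references); no rearrangement detection — a scaffold spanning a breakpoint is
flagged, not split; ungapped anchors and ungapped read placement (indel-aware
alignment is out of scope); the built-in mapper is quadratic in the worst
case and meant for desk-scale genomes; open-gap sizes are reference-distance
estimates and can be wrong where the strains differ structurally between the
flanking anchors.
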