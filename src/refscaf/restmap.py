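"""In-silico restriction digestion and fragment-map comparison.

A physical (restriction-site) map is a strong genome-scale check on an
assembly: if the assembly is correctly ordered and sized, an in-silico digest
must reproduce the experimentally observed fragment count, and fragment sizes
must agree within the sizing error of pulsed-field gels (a few percent).

Cuts are placed at the motif start: at gel-sizing tolerance the offset of the
cut within the recognition site is irrelevant, and fragment *sizes* are the
quantity compared. The comparison is order-preserving (both maps are anchored
to genome position), not multiset matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .seqio import check_dna

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_revcomp(motif: str) -> str:
    return motif.translate(_IUPAC_COMP)[::-1]


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for c in motif:
        try:
            parts.append(f"[{IUPAC[c]}]")
        except KeyError:
            raise ValueError(f"invalid IUPAC code {c!r} in motif {motif!r}")
    return re.compile("(?=" + "".join(parts) + ")")   # overlapping matches


@dataclass(frozen=True)
class RecognitionSite:
    name: str
    motif: str

    def __post_init__(self):
        if len(self.motif) < 4:
            raise ValueError("recognition motif must be at least 4 bp")
        _iupac_regex(self.motif)   # validates codes

    @property
    def palindromic(self) -> bool:
        return iupac_revcomp(self.motif) == self.motif


# SfiI: interrupted palindrome, the classic physical-mapping enzyme
SFI_I = RecognitionSite("SfiI", "GGCCNNNNNGGCC")

ENZYMES = {"SfiI": SFI_I,
           "NotI": RecognitionSite("NotI", "GCGGCCGC"),
           "EcoRI": RecognitionSite("EcoRI", "GAATTC")}


@dataclass(frozen=True)
class FragmentSet:
    topology: str                      # linear | circular
    fragments: tuple[int, ...]         # lengths in genome-position order
    cut_positions: tuple[int, ...] = field(default=(), compare=False)

    def __post_init__(self):
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")
        if any(f <= 0 for f in self.fragments):
            raise ValueError("fragment lengths must be positive")

    @property
    def total(self) -> int:
        return sum(self.fragments)


def find_sites(sequence: str, site: RecognitionSite, topology: str = "linear",
               ) -> list[int]:
    """Start positions of the recognition motif (both strands collapsed)."""
    sequence = check_dna(sequence)
    L, m = len(sequence), len(site.motif)
    template = sequence + sequence[:m - 1] if topology == "circular" else sequence
    positions: set[int] = set()
    motifs = [site.motif] if site.palindromic else [site.motif,
                                                   iupac_revcomp(site.motif)]
    for motif in motifs:
        for match in _iupac_regex(motif).finditer(template):
            pos = match.start()
            if pos < L:
                positions.add(pos % L)
    return sorted(positions)


def digest(sequence: str, site: RecognitionSite, topology: str = "linear",
           ) -> FragmentSet:
    """Cut at every motif occurrence; fragments listed in position order.

    Linear templates keep both end fragments; circular templates join
    last-to-first. A template with no site yields one full-length fragment.
    """
    if topology not in ("linear", "circular"):
        raise ValueError(f"bad topology {topology!r}")
    cuts = find_sites(sequence, site, topology)
    L = len(sequence)
    if not cuts:
        return FragmentSet(topology, (L,), ())
    if topology == "linear":
        bounds = [0] + cuts + [L]
        frags = tuple(b - a for a, b in zip(bounds, bounds[1:]) if b > a)
    else:
        frags = tuple((b - a) % L or L
                      for a, b in zip(cuts, cuts[1:] + [cuts[0]]))
    return FragmentSet(topology, frags, tuple(cuts))


@dataclass(frozen=True)
class FragmentComparison:
    count_match: bool
    n_predicted: int
    n_experimental: int
    pairs: tuple[tuple[int, int, bool], ...] = ()   # (predicted, experimental, ok)

    @property
    def all_matched(self) -> bool:
        return self.count_match and all(ok for _, _, ok in self.pairs)

    @property
    def outliers(self) -> list[int]:
        return [i for i, (_, _, ok) in enumerate(self.pairs) if not ok]


def compare_fragment_sets(predicted: FragmentSet | Sequence[int],
                          experimental: FragmentSet | Sequence[int],
                          rel_tol: float = 0.03) -> FragmentComparison:
    """Order-preserving fragment-size comparison with relative tolerance.

    Fragment counts must agree for pairwise comparison; a pair matches iff
    |a - b| <= rel_tol * max(a, b). The default 3% tolerance is the sizing
    error of pulsed-field gel electrophoresis.
    """
    pf = tuple(predicted.fragments if isinstance(predicted, FragmentSet)
               else predicted)
    ef = tuple(experimental.fragments if isinstance(experimental, FragmentSet)
               else experimental)
    if len(pf) != len(ef):
        return FragmentComparison(False, len(pf), len(ef))
    pairs = tuple((a, b, abs(a - b) <= rel_tol * max(a, b))
                  for a, b in zip(pf, ef))
    return FragmentComparison(True, len(pf), len(ef), pairs)


def fragments_to_tsv(frags: FragmentSet) -> str:
    lines = ["fragment\tstart_cut\tlength"]
    cuts = frags.cut_positions or (0,)
    for i, ln in enumerate(frags.fragments):
        start = cuts[i] if i < len(cuts) else 0
        lines.append(f"{i + 1}\t{start}\t{ln}")
    return "\n".join(lines) + "\n"


def parse_experimental_map(text: str) -> tuple[int, ...]:
    """Two-column TSV (fragment order, size bp) -> ordered sizes."""
    sizes = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        order, size = line.split("\t")[:2]
        sizes.append((int(order), int(size)))
    sizes.sort()
    return tuple(s for _, s in sizes)
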