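"""In-silico PCR: product-size prediction from a primer pair on a template.

Used to verify structural differences between an assembly and its reference
— e.g. primers flanking an operon that amplify a short product only from the
genome in which the operon is deleted. Default matching is exact (predicted
sizes in the strict sense); a per-primer mismatch budget can be allowed, but
the 3'-terminal base must always match exactly, since 3' mismatches abolish
extension in a real reaction.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np

from .restmap import IUPAC
from .seqio import check_dna, revcomp

_MASK = {"A": 1, "C": 2, "G": 4, "T": 8}
for code, bases in IUPAC.items():
    _MASK.setdefault(code, sum(_MASK[b] for b in bases))


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both given 5'->3'."""

    fwd: str
    rev: str
    max_product: int = 10_000
    max_mismatches: int = 0

    def __post_init__(self):
        for name, p in (("fwd", self.fwd), ("rev", self.rev)):
            if len(p) < 15:
                raise ValueError(f"{name} primer shorter than 15 nt")
            bad = set(p.upper()) - set(_MASK)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC symbols {sorted(bad)}")
        if self.max_product <= max(len(self.fwd), len(self.rev)):
            raise ValueError("max_product must exceed the primer lengths")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class Product:
    start: int      # 5' end of the forward primer site on the template
    end: int        # one past the 3' end of the reverse primer site
    length: int

    @property
    def length_kb(self) -> float:
        return round(self.length / 1000, 2)


def _encode_template(template: str) -> np.ndarray:
    arr = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
    out = np.zeros(arr.shape, dtype=np.uint8)
    for base, mask in (("A", 1), ("C", 2), ("G", 4), ("T", 8)):
        out[arr == ord(base)] = mask
    return out   # N (and anything else) -> 0: binds nothing


def _primer_sites(tmpl: np.ndarray, primer: str, max_mm: int,
                  three_prime_offset: int) -> list[int]:
    """Template positions where `primer` binds with <= max_mm mismatches and
    an exact match at the 3'-terminal offset."""
    m = len(primer)
    n = len(tmpl) - m + 1
    if n <= 0:
        return []
    masks = [_MASK[c] for c in primer.upper()]
    mism = np.zeros(n, dtype=np.int32)
    for k, pmask in enumerate(masks):
        mism += (tmpl[k:k + n] & pmask) == 0
    ok = mism <= max_mm
    k = three_prime_offset
    ok &= (tmpl[k:k + n] & masks[k]) != 0
    return np.flatnonzero(ok).tolist()


def predict_products(template: str, pair: PrimerPair,
                     topology: str = "linear") -> list[Product]:
    """All products the pair would amplify from the template.

    A product is formed by a forward-primer site at i and a reverse-primer
    site (the reverse complement of `rev` on the forward strand) ending at
    j + |rev|, with i before j (wrapping on circular templates) and product
    length (j + |rev|) - i within max_product. Product length is never less
    than the two primer lengths combined.
    """
    if topology not in ("linear", "circular"):
        raise ValueError(f"bad topology {topology!r}")
    template = check_dna(template, "template")
    L = len(template)
    scan = template + template[:min(L, pair.max_product)] \
        if topology == "circular" else template
    tmpl = _encode_template(scan)

    fwd_sites = [p for p in _primer_sites(tmpl, pair.fwd, pair.max_mismatches,
                                          len(pair.fwd) - 1) if p < L]
    # reverse primer binds the reverse strand: scan its revcomp on the forward
    # strand; the primer's 3' terminus maps to offset 0 of the pattern
    rc = revcomp(pair.rev.upper())
    rev_sites = _primer_sites(tmpl, rc, pair.max_mismatches, 0)
    m_rev, m_fwd = len(pair.rev), len(pair.fwd)

    products = []
    for i in fwd_sites:
        lo = bisect_left(rev_sites, i + m_fwd)
        hi = bisect_right(rev_sites, i + pair.max_product - m_rev)
        for j in rev_sites[lo:hi]:
            end = j + m_rev
            products.append(Product(i, end if end <= L else end - L, end - i))
    return sorted(products, key=lambda p: (p.start, p.length))
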