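"""Independent brute-force oracles for the randomized equivalence tests.

Each is a direct, quadratic (or worse) restatement of the operation's
definition, sharing no code with the implementation it checks.
"""

from __future__ import annotations

from refscaf.seqio import revcomp

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}


def iupac_rc(motif: str) -> str:
    return "".join(_COMP[c] for c in reversed(motif))


def maximal_exact_matches(query: str, reference: str, min_len: int,
                          ) -> set[tuple[int, int, int, int, str]]:
    """All maximal exact matches >= min_len, both strands, by diagonal walk.

    Returns (q_start, q_end, r_start, r_end, strand) with q coordinates on the
    forward query. N never matches anything.
    """
    out: set[tuple[int, int, int, int, str]] = set()
    qlen = len(query)
    for strand, q in (("forward", query), ("reverse", revcomp(query))):
        nq, nr = len(q), len(reference)
        for d in range(-nq + 1, nr):
            qpos = max(0, -d)
            run = 0
            while qpos <= nq:
                ok = (qpos < nq and 0 <= qpos + d < nr
                      and q[qpos] != "N" and q[qpos] == reference[qpos + d])
                if ok:
                    run += 1
                else:
                    if run >= min_len:
                        qs, qe = qpos - run, qpos
                        if strand == "forward":
                            out.add((qs, qe, qs + d, qe + d, strand))
                        else:
                            out.add((qlen - qe, qlen - qs, qs + d, qe + d, strand))
                    run = 0
                qpos += 1
    return out


def longest_overlap(left: str, right: str, min_overlap: int,
                    max_mismatch_rate: float) -> int | None:
    """Longest suffix/prefix overlap within tolerance; N mismatches everything."""
    for ov in range(min(len(left), len(right)), min_overlap - 1, -1):
        lseg, rseg = left[len(left) - ov:], right[:ov]
        mm = sum(a != b or a == "N" or b == "N" for a, b in zip(lseg, rseg))
        if mm <= int(max_mismatch_rate * ov):
            return ov
    return None


def digest_positions(sequence: str, motif: str, topology: str) -> list[int]:
    """Every motif match position by per-character IUPAC scan, both strands."""
    L, m = len(sequence), len(motif)
    template = sequence + sequence[:m - 1] if topology == "circular" else sequence
    motifs = {motif, iupac_rc(motif)}
    hits = set()
    for mo in motifs:
        for i in range(min(len(template) - m + 1, L if topology == "circular"
                           else len(template) - m + 1)):
            if all(template[i + k] in IUPAC_SETS[mo[k]] for k in range(m)):
                if i < L:
                    hits.add(i % L)
    return sorted(hits)


def digest_fragments(sequence: str, motif: str, topology: str) -> list[int]:
    cuts = digest_positions(sequence, motif, topology)
    L = len(sequence)
    if not cuts:
        return [L]
    if topology == "linear":
        bounds = [0] + cuts + [L]
        return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return [(b - a) % L or L for a, b in zip(cuts, cuts[1:] + [cuts[0]])]


def _binds(template: str, pos: int, primer: str, max_mm: int,
           three_prime_offset: int) -> bool:
    mm = 0
    for k, c in enumerate(primer):
        t = template[pos + k]
        hit = t in IUPAC_SETS.get(c, set()) and t != "N"
        if not hit:
            if k == three_prime_offset:
                return False
            mm += 1
    return mm <= max_mm


def pcr_products(template: str, fwd: str, rev: str, max_product: int,
                 topology: str = "linear", max_mm: int = 0) -> list[int]:
    """Product lengths from an exhaustive double position scan."""
    L = len(template)
    ext = template + template[:min(L, max_product)] if topology == "circular" \
        else template
    rc = revcomp(rev)
    fwd_sites = [i for i in range(len(ext) - len(fwd) + 1)
                 if i < L and _binds(ext, i, fwd, max_mm, len(fwd) - 1)]
    rev_sites = [j for j in range(len(ext) - len(rc) + 1)
                 if _binds(ext, j, rc, max_mm, 0)]
    lengths = []
    for i in fwd_sites:
        for j in rev_sites:
            if j >= i + len(fwd) and (j + len(rev)) - i <= max_product:
                lengths.append((j + len(rev)) - i)
    return sorted(lengths)


def expand_pileup(alignments, reference_length: int) -> list[list[tuple[str, int]]]:
    """Naive per-read expansion of ungapped full-M alignments into columns."""
    cols: list[list[tuple[str, int]]] = [[] for _ in range(reference_length)]
    for a in alignments:
        if not a.is_mapped or a.multi:
            continue
        for k, base in enumerate(a.seq):
            cols[a.pos + k].append((base, a.quals[k]))
    return cols
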