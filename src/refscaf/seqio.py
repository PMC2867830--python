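"""Sequence and format I/O helpers shared across the pipeline.

FASTA/FASTQ go through Biopython, SAM through pysam. AGP 2.1 and BED are
simple tab-delimited formats written directly. All internal coordinates are
0-based half-open; AGP rows are converted to 1-based inclusive on output.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, name: str = "sequence") -> str:
    """Uppercase and validate a DNA string over {A,C,G,T,N}."""
    s = seq.upper()
    if not s:
        raise ValueError(f"{name} is empty")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-DNA symbols: {sorted(bad)!r}")
    return s


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly wrapped) multi-FASTA into an ordered {id: sequence} dict."""
    with _open_text(path) as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: dict[str, str] | Iterable[tuple[str, str]],
                width: int = 70) -> None:
    items = records.items() if isinstance(records, dict) else records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[tuple]:
    """Yield (id, seq1, qual1, seq2, qual2) from two synchronised FASTQ files.

    Raises a ValueError naming the record index on malformed or desynchronised
    input.
    """
    with _open_text(path1) as fh1, _open_text(path2) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        for i, (r1, r2) in enumerate(zip(it1, it2)):
            try:
                q1 = r1.letter_annotations["phred_quality"]
                q2 = r2.letter_annotations["phred_quality"]
            except KeyError as exc:  # pragma: no cover - SeqIO validates
                raise ValueError(f"FASTQ record {i}: missing qualities") from exc
            yield r1.id, str(r1.seq).upper(), q1, str(r2.seq).upper(), q2
        if next(it1, None) is not None or next(it2, None) is not None:
            raise ValueError("paired FASTQ files have different record counts")


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, list[int]]]) -> None:
    """Write (id, seq, phred list) tuples as FASTQ."""
    with open(path, "w") as fh:
        for name, seq, quals in records:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{name}\n{seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# AGP 2.1

def agp_rows_to_text(object_id: str, rows: list[dict]) -> str:
    """Serialise AGP 2.1 rows.

    Each row dict carries 0-based half-open `obj_start`/`obj_end` plus either a
    component (`component_id`, `comp_start`, `comp_end`, `orientation`) or a gap
    (`gap_length`, `gap_type`, `linkage`, `evidence`).
    """
    lines = ["##agp-version\t2.1"]
    for i, row in enumerate(rows, start=1):
        obj_beg = row["obj_start"] + 1
        obj_end = row["obj_end"]
        if "component_id" in row:
            lines.append("\t".join(map(str, (
                object_id, obj_beg, obj_end, i, "W",
                row["component_id"], row["comp_start"] + 1, row["comp_end"],
                row["orientation"],
            ))))
        else:
            lines.append("\t".join(map(str, (
                object_id, obj_beg, obj_end, i, "U" if row.get("unknown") else "N",
                row["gap_length"], row.get("gap_type", "scaffold"),
                row.get("linkage", "yes"), row.get("evidence", "align_genus"),
            ))))
    return "\n".join(lines) + "\n"


def parse_agp(text: str) -> list[dict]:
    """Parse AGP 2.1 text back into row dicts (0-based half-open coordinates)."""
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        row = {"object_id": f[0], "obj_start": int(f[1]) - 1, "obj_end": int(f[2])}
        if f[4] == "W":
            row.update(component_id=f[5], comp_start=int(f[6]) - 1,
                       comp_end=int(f[7]), orientation=f[8])
        else:
            row.update(gap_length=int(f[5]), gap_type=f[6], linkage=f[7],
                       evidence=f[8] if len(f) > 8 else "")
        rows.append(row)
    return rows


def write_bed(path: str | Path, intervals: Iterable[tuple[str, int, int, str]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
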