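"""Readers and writers for the standard formats used by the toolkit."""

from __future__ import annotations

import gzip
from typing import Iterable, Mapping

from Bio import SeqIO


def _open(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str) -> dict[str, str]:
    """FASTA records as a name -> uppercase sequence dict."""
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 80) -> None:
    with _open(path, "wt") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq_pair(
    pairs: Iterable[tuple[str, str, str]], prefix: str
) -> tuple[str, str]:
    """Write (name, read1, read2) triples to ``<prefix>_1.fastq`` and
    ``<prefix>_2.fastq`` with uniform quality."""
    p1, p2 = f"{prefix}_1.fastq", f"{prefix}_2.fastq"
    with _open(p1, "wt") as f1, _open(p2, "wt") as f2:
        for name, r1, r2 in pairs:
            f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")
    return p1, p2


def read_fastq_pairs(path1: str, path2: str) -> list[tuple[str, str, str]]:
    """Read paired FASTQ files back into (name, read1, read2) triples;
    raises on unpaired or truncated input."""
    with _open(path1) as f1, _open(path2) as f2:
        recs1 = list(SeqIO.parse(f1, "fastq"))
        recs2 = list(SeqIO.parse(f2, "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError(f"unpaired FASTQ: {len(recs1)} vs {len(recs2)} records")
    out = []
    for a, b in zip(recs1, recs2):
        na, nb = a.id.rsplit("/", 1)[0], b.id.rsplit("/", 1)[0]
        if na != nb:
            raise ValueError(f"read name mismatch: {a.id} vs {b.id}")
        out.append((na, str(a.seq).upper(), str(b.seq).upper()))
    return out
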