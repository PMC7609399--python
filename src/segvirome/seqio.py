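"""FASTA/FASTQ I/O helpers (thin wrappers over Bio.SeqIO) and paired reads."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    seq2: str


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered mapping id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq_pair(
    prefix: str | Path, pairs: Iterable[ReadPair], quality_char: str = "I"
) -> tuple[Path, Path]:
    """Write 4-line paired FASTQ files ``<prefix>_R1.fastq`` / ``_R2.fastq``."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq")
    p2 = prefix.with_name(prefix.name + "_R2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for pair in pairs:
            f1.write(
                f"@{pair.read_id}/1\n{pair.seq1}\n+\n{quality_char * len(pair.seq1)}\n"
            )
            f2.write(
                f"@{pair.read_id}/2\n{pair.seq2}\n+\n{quality_char * len(pair.seq2)}\n"
            )
    return p1, p2


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) tuples; the /1 /2 mate suffix is kept as written."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def iter_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Yield mate pairs from two FASTQ files, enforcing id agreement.

    Raises ``ValueError`` naming the first offending record on mate-count
    or id mismatch.
    """
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    n = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            lone = r1 if r2 is None else r2
            raise ValueError(
                f"mate-count mismatch between R1/R2 at record {n + 1} ({lone.id})"
            )
        id1 = r1.id.removesuffix("/1")
        id2 = r2.id.removesuffix("/2")
        if id1 != id2:
            raise ValueError(f"mate id mismatch at record {n + 1}: {r1.id} vs {r2.id}")
        n += 1
        yield ReadPair(id1, str(r1.seq).upper(), str(r2.seq).upper())
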