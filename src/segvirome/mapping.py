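"""Ungapped end-to-end read mapping via shared k-mer seeds, plus SAM import.

The built-in mapper places each read at its best-scoring (fewest
mismatches) ungapped end-to-end position on either strand of any contig,
found by probing read k-mers against a contig k-mer position index.  Ties
are broken to the lowest (contig_id, start0); a read whose best score is
achieved at more than one placement is flagged ``ambiguous`` so terminus
support can exclude it (segments of one virus share terminal sequences,
and reads from those windows tie across segments).

Gapped alignments from external mappers enter through ``import_sam``;
only pure-match records (CIGAR M/=/X) are consumed, so downstream segment
calls are comparable between the two routes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from segvirome.kmers import encode_sequence, kmer_codes
from segvirome.seqio import revcomp

logger = logging.getLogger(__name__)

DEFAULT_SEED_K = 15
DEFAULT_MAX_MISMATCH_FRAC = 0.05


@dataclass
class ReadAlignment:
    read_id: str
    contig_id: str
    start0: int
    end0: int
    strand: str
    n_mismatches: int
    ambiguous: bool = False


class ContigIndex:
    """Plus-strand k-mer position index over a set of contigs."""

    def __init__(self, contigs: dict[str, str], k: int = DEFAULT_SEED_K):
        self.k = k
        self.ids = sorted(contigs)
        self.seqs = {cid: contigs[cid] for cid in self.ids}
        self.arrays = {cid: encode_sequence(contigs[cid]) for cid in self.ids}
        self.positions: dict[int, list[tuple[str, int]]] = {}
        for cid in self.ids:
            codes = kmer_codes(contigs[cid], k)
            for pos, code in enumerate(codes.tolist()):
                self.positions.setdefault(code, []).append((cid, pos))

    def candidates(self, seq: str) -> set[tuple[str, int]]:
        """Candidate (contig_id, start0) end-to-end placements for *seq*."""
        k = self.k
        n = len(seq)
        out: set[tuple[str, int]] = set()
        codes = kmer_codes(seq, k)
        if codes.size == 0:
            return out
        # non-overlapping probes; at least one is error-free w.h.p.
        for off in range(0, codes.size, k):
            for cid, pos in self.positions.get(int(codes[off]), ()):
                start = pos - off
                if 0 <= start and start + n <= len(self.seqs[cid]):
                    out.add((cid, start))
        return out

    def count_mismatches(self, cid: str, start: int, read_arr: np.ndarray) -> int:
        ref = self.arrays[cid][start : start + read_arr.size]
        return int(np.count_nonzero(ref != read_arr))


def map_reads(
    reads: list[tuple[str, str]],
    contigs: dict[str, str],
    seed_k: int = DEFAULT_SEED_K,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    index: ContigIndex | None = None,
) -> tuple[list[ReadAlignment], list[str]]:
    """Best ungapped end-to-end placement per read on either strand.

    *reads* is (read_id, sequence) tuples; *contigs* maps id -> sequence.
    Returns (alignments, unmapped read ids).  Unmapped is a status, not
    an error.
    """
    if not contigs:
        raise ValueError("contigs must be non-empty")
    if index is None:
        index = ContigIndex(contigs, seed_k)
    alignments: list[ReadAlignment] = []
    unmapped: list[str] = []
    for read_id, seq in reads:
        hit = _best_placement(seq, index, max_mismatch_frac)
        if hit is None:
            unmapped.append(read_id)
        else:
            cid, start, strand, mm, ambiguous = hit
            alignments.append(
                ReadAlignment(read_id, cid, start, start + len(seq), strand, mm, ambiguous)
            )
    return alignments, unmapped


def _best_placement(
    seq: str, index: ContigIndex, max_mismatch_frac: float
) -> tuple[str, int, str, int, bool] | None:
    n = len(seq)
    max_mm = int(max_mismatch_frac * n)
    best: tuple[int, str, int, str] | None = None  # (mm, contig, start, strand)
    n_best = 0
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        arr = encode_sequence(oriented)
        for cid, start in sorted(index.candidates(oriented)):
            mm = index.count_mismatches(cid, start, arr)
            if mm > max_mm:
                continue
            key = (mm, cid, start, strand)
            if best is None or mm < best[0]:
                best, n_best = key, 1
            elif mm == best[0]:
                n_best += 1
                if (cid, start, strand) < (best[1], best[2], best[3]):
                    best = key
    if best is None:
        return None
    mm, cid, start, strand = best
    return cid, start, strand, mm, n_best > 1


def brute_force_map(
    seq: str, contigs: dict[str, str], max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC
) -> tuple[str, int, str, int] | None:
    """Exhaustive all-position, both-strand scan; oracle for the mapper."""
    n = len(seq)
    max_mm = int(max_mismatch_frac * n)
    best = None
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        arr = encode_sequence(oriented)
        for cid in sorted(contigs):
            ref = encode_sequence(contigs[cid])
            for start in range(0, len(ref) - n + 1):
                mm = int(np.count_nonzero(ref[start : start + n] != arr))
                if mm > max_mm:
                    continue
                key = (mm, cid, start, strand)
                if best is None or key[0] < best[0] or (
                    key[0] == best[0] and (cid, start, strand) < (best[1], best[2], best[3])
                ):
                    best = key
    if best is None:
        return None
    mm, cid, start, strand = best
    return cid, start, strand, mm


def import_sam(path: str | Path) -> list[ReadAlignment]:
    """Import mapped records from a SAM file.

    Flags 0/16 set the strand; CIGAR M/=/X records are consumed and
    records containing I/D/S/H operations are skipped with a logged
    count.  SAM's 1-based coordinates are converted to 0-based half-open
    at this boundary.
    """
    skipped = 0
    alignments: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            ops = {op for op, _ in (rec.cigartuples or [])}
            # 0=M, 7==, 8=X are acceptable; 1=I, 2=D, 4=S, 5=H are not
            if ops - {0, 7, 8}:
                skipped += 1
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            alignments.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    contig_id=rec.reference_name,
                    start0=rec.reference_start,
                    end0=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    n_mismatches=int(nm),
                )
            )
    if skipped:
        logger.info("import_sam: skipped %d records with indel/clip CIGARs", skipped)
    return alignments


def alignments_to_tsv(alignments: list[ReadAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcontig_id\tstart0\tend0\tstrand\tn_mismatches\tambiguous\n")
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.contig_id}\t{a.start0}\t{a.end0}\t{a.strand}\t"
                f"{a.n_mismatches}\t{int(a.ambiguous)}\n"
            )
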