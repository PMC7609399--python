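"""Greedy overlap assembly of substitution-only short reads.

A deliberately minimal overlap assembler for desk-scale data: contigs are
grown greedily from seed reads by repeated best suffix-prefix overlap
merges (longest extension, then fewest mismatches, then lexicographic
read id), in both orientations, requiring overlap >= ``min_overlap`` with
mismatch fraction <= ``max_mismatch_frac``.  After a contig stops
growing, every read consistent with it end-to-end is marked consumed, so
coverage depth does not multiply work.  The assembler is pluggable:
pre-assembled contigs can be supplied as FASTA and bypass it entirely.

Overlap candidates are located through an exact k-mer prefix index, so
two sequences sharing only a short terminal motif (shorter than
``min_overlap``) can never be merged — which is what keeps segments of
one virus, which share their termini, from chimerising.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from segvirome.kmers import encode_sequence, kmer_codes
from segvirome.seqio import ReadPair, read_fasta, revcomp

DEFAULT_MIN_OVERLAP = 50
DEFAULT_MAX_MISMATCH_FRAC = 0.05
_PREFIX_K = 21


@dataclass
class Contig:
    id: str
    sequence: str
    source: str = "builtin_assembler"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: contig must be non-empty")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"{self.id}: contig alphabet must be ACGTN")


def load_contigs(path: str | Path) -> list[Contig]:
    return [
        Contig(cid, seq.upper(), source="imported")
        for cid, seq in read_fasta(path).items()
    ]


def _as_reads(reads) -> list[tuple[str, str]]:
    if reads and isinstance(reads[0], ReadPair):
        out = []
        for pair in reads:
            out.append((pair.read_id + "/1", pair.seq1))
            out.append((pair.read_id + "/2", pair.seq2))
        return out
    return list(reads)


_N_PREFIX_PROBES = 5


class _ReadStore:
    def __init__(self, reads: list[tuple[str, str]], k: int):
        self.ids = [r[0] for r in reads]
        self.fwd = [r[1] for r in reads]
        self.rev = [revcomp(r[1]) for r in reads]
        self.fwd_arr = [encode_sequence(s) for s in self.fwd]
        self.rev_arr = [encode_sequence(s) for s in self.rev]
        self.used = np.zeros(len(reads), dtype=bool)
        self.k = k
        # k-mers at several prefix offsets of each oriented read, so one
        # substitution error (in read or contig) cannot hide an overlap
        self.prefix: dict[int, list[tuple[int, int, int]]] = {}
        for i, seqs in enumerate(zip(self.fwd, self.rev)):
            for strand, s in enumerate(seqs):
                for probe in range(_N_PREFIX_PROBES):
                    off = probe * k
                    window = s[off : off + k]
                    if len(window) < k or "N" in window:
                        continue
                    code = int(kmer_codes(window, k)[0])
                    self.prefix.setdefault(code, []).append((i, strand, off))

    def oriented(self, i: int, strand: int) -> tuple[str, np.ndarray]:
        return (self.fwd[i], self.fwd_arr[i]) if strand == 0 else (self.rev[i], self.rev_arr[i])


def _extend_right(
    contig: str,
    store: _ReadStore,
    min_overlap: int,
    max_mismatch_frac: float,
) -> tuple[str, list[int]]:
    """Greedily extend *contig* rightward; returns (sequence, reads used)."""
    k = store.k
    consumed: list[int] = []
    arr = encode_sequence(contig)
    max_read = max((len(s) for s in store.fwd), default=0)
    while True:
        L = arr.size
        best = None  # (-extension, mismatches, read_id, idx, strand, overlap)
        lo = max(0, L - max_read)
        codes = kmer_codes(contig[lo:], k)
        n_codes = (L - lo) - k + 1 if "N" not in contig[lo:] else 0
        seen: set[tuple[int, int, int]] = set()
        for rel in range(n_codes):
            for i, strand, off in store.prefix.get(int(codes[rel]), ()):
                if store.used[i]:
                    continue
                start = lo + rel - off  # implied read alignment start on contig
                ov = L - start
                if ov < min_overlap or (i, strand, start) in seen:
                    continue
                seen.add((i, strand, start))
                seq, sarr = store.oriented(i, strand)
                ext = len(seq) - ov
                if ext <= 0 or ov > len(seq) or start < 0:
                    continue
                mm = int(np.count_nonzero(arr[start:] != sarr[:ov]))
                if mm > max_mismatch_frac * ov:
                    continue
                key = (-ext, mm, store.ids[i], i, strand, ov)
                if best is None or key[:3] < best[:3]:
                    best = key
        if best is None:
            return contig, consumed
        _, _, _, i, strand, ov = best
        seq, _ = store.oriented(i, strand)
        contig = contig + seq[ov:]
        arr = encode_sequence(contig)
        store.used[i] = True
        consumed.append(i)


def _mark_contained(contig: str, store: _ReadStore, max_mismatch_frac: float) -> None:
    """Mark every unused read placeable end-to-end on *contig* as used."""
    k = store.k
    positions: dict[int, int] = {}
    for pos, code in enumerate(kmer_codes(contig, k).tolist()):
        positions.setdefault(code, pos)
    arr = encode_sequence(contig)
    L = arr.size
    for i in np.nonzero(~store.used)[0]:
        for strand in (0, 1):
            seq, sarr = store.oriented(i, strand)
            n = len(seq)
            placed = False
            codes = kmer_codes(seq, k)
            for off in range(0, max(codes.size, 1), k):
                if off >= codes.size:
                    break
                pos = positions.get(int(codes[off]))
                if pos is None:
                    continue
                start = pos - off
                if start < 0 or start + n > L:
                    continue
                mm = int(np.count_nonzero(arr[start : start + n] != sarr))
                if mm <= max_mismatch_frac * n:
                    store.used[i] = True
                    placed = True
                    break
            if placed:
                break


def assemble(
    reads,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> list[Contig]:
    """Assemble reads (ReadPair list or (id, seq) tuples) into contigs.

    Deterministic: seeds are taken in input order, and merge choice is
    longest extension, then fewest mismatches, then lexicographic read
    id.  Zero merges is a valid outcome (every read its own contig).
    """
    read_list = _as_reads(reads)
    if not read_list:
        return []
    if min_overlap < _PREFIX_K:
        # candidate location needs a full k-mer inside every admissible overlap
        raise ValueError(f"min_overlap must be >= {_PREFIX_K}")
    store = _ReadStore(read_list, _PREFIX_K)
    contigs: list[Contig] = []
    n = len(read_list)
    for seed in range(n):
        if store.used[seed]:
            continue
        store.used[seed] = True
        contig = store.fwd[seed]
        contig, _ = _extend_right(contig, store, min_overlap, max_mismatch_frac)
        contig = revcomp(contig)
        contig, _ = _extend_right(contig, store, min_overlap, max_mismatch_frac)
        contig = revcomp(contig)
        _mark_contained(contig, store, max_mismatch_frac)
        contigs.append(Contig(f"contig_{len(contigs) + 1:05d}", contig))
    return contigs
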