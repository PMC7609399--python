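"""Vectorised 2-bit k-mer encoding with strand-collapsed canonical form.

A k-mer and its reverse complement are collapsed onto the lexicographically
smaller 2-bit code, so indexing and containment queries are strand
agnostic.  Windows containing any non-ACGT base are dropped rather than
encoded.  k must be odd so that no k-mer is its own reverse complement and
the canonical form is well defined.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def encode_sequence(seq: str) -> np.ndarray:
    """2-bit codes for *seq*; non-ACGT bases become 255."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Forward-strand integer codes of all valid k-length windows of *seq*.

    Windows containing a non-ACGT base are omitted.  Returns int64 codes
    (base-4 big-endian packing); order follows window position.
    """
    if k < 1 or k > 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    codes = encode_sequence(seq)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes != 255
    ok = (
        np.convolve(valid.astype(np.int64), np.ones(k, dtype=np.int64), "valid") == k
    )
    vals = np.where(valid, codes, 0).astype(np.int64)
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        out = (out << 2) | vals[i : i + n]
    return out[ok]


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of packed k-mer codes (complement = 3 - code)."""
    out = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        out = (out << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return out


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (min of forward / reverse-complement) codes per window."""
    if k % 2 == 0:
        raise ValueError("k must be odd for a well-defined canonical form")
    fwd = kmer_codes(seq, k)
    if fwd.size == 0:
        return fwd
    return np.minimum(fwd, revcomp_codes(fwd, k))


def containment(seq: str, k: int, sorted_index: np.ndarray) -> float:
    """Fraction of valid k-mer windows of *seq* found in *sorted_index*.

    *sorted_index* is a sorted int64 array of canonical k-mer codes.
    Returns 0.0 when the read has no valid window.
    """
    kmers = canonical_kmers(seq, k)
    if kmers.size == 0 or sorted_index.size == 0:
        return 0.0
    pos = np.searchsorted(sorted_index, kmers)
    inside = pos < sorted_index.size
    hits = np.zeros(kmers.size, dtype=bool)
    hits[inside] = sorted_index[pos[inside]] == kmers[inside]
    return float(hits.sum()) / kmers.size
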