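"""Genome-set grouping by conserved terminal sequences.

Segments of one multi-segment RNA virus share conserved 5'/3' terminal
sequences, so full-length segments can be attributed to viruses by
clustering on terminal-window dissimilarity.  dsRNA has no intrinsic
strand label, so each segment is first oriented to its coding strand
(by the frame of its best RdRp hit, or failing that by the strand with
the longest stop-free reading-frame run).  The dissimilarity between two
segments is the mean of the per-side normalised edit distances between
their 5' and 3' windows; single-linkage clustering at a threshold
``theta`` forms genome sets, because shared termini are transitive
evidence.

Two honesty mechanisms mirror how such groupings are reported in
practice: sets whose minimum inter-set distance falls in the grey band
(theta, theta_ambig] are cross-listed as mutually ambiguous rather than
force-merged, and a set containing more than one RdRp-bearing segment is
flagged — that is the situation where several viruses' RdRp segments
share termini and their genome sets cannot be distinguished.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from segvirome.otus import PanelHit
from segvirome.seqio import revcomp

DEFAULT_W = 30
DEFAULT_THETA = 0.2
DEFAULT_THETA_AMBIG = 0.35

_BASES = "ACGT"


@dataclass
class TerminalProfile:
    segment_id: str
    window5: str
    window3: str  # last w nt, stored 5'->3' on the oriented strand

    @classmethod
    def from_sequence(cls, segment_id: str, seq: str, w: int = DEFAULT_W) -> "TerminalProfile":
        if w > len(seq) // 2:
            raise ValueError(f"{segment_id}: w={w} exceeds half the segment length")
        return cls(segment_id, seq[:w].upper(), seq[-w:].upper())


@dataclass
class GenomeSet:
    set_id: str
    segment_ids: list[str]
    pfm5: np.ndarray = field(default=None, repr=False)
    pfm3: np.ndarray = field(default=None, repr=False)
    ambiguous_with: list[str] = field(default_factory=list)
    rdrp_segment_ids: list[str] = field(default_factory=list)

    @property
    def ambiguous(self) -> bool:
        return bool(self.ambiguous_with) or len(self.rdrp_segment_ids) >= 2


def longest_orf_run(seq: str) -> int:
    """Longest stop-free codon run over the three forward frames, in nt."""
    best = 0
    stops = {"TAA", "TAG", "TGA"}
    for off in range(3):
        run = 0
        for i in range(off, len(seq) - 2, 3):
            if seq[i : i + 3] in stops:
                run = 0
            else:
                run += 3
                best = max(best, run)
    return best


def orient_segment(segment: str, rdrp_hits: list[PanelHit] | None = None) -> str:
    """Return *segment* on its coding strand.

    If the best RdRp hit lies on a negative frame the segment is
    reverse-complemented; without hits the strand with the longest
    stop-free reading-frame run wins (plus strand on ties).
    """
    if rdrp_hits:
        return revcomp(segment) if rdrp_hits[0].frame < 0 else segment
    fwd = longest_orf_run(segment)
    rev = longest_orf_run(revcomp(segment))
    return revcomp(segment) if rev > fwd else segment


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def terminal_distance(a: TerminalProfile, b: TerminalProfile) -> float:
    """Mean of per-side normalised edit distances over the 5' and 3' windows."""
    if len(a.window5) != len(b.window5) or len(a.window3) != len(b.window3):
        raise ValueError("profiles must use equal window lengths")
    d5 = edit_distance(a.window5, b.window5) / len(a.window5)
    d3 = edit_distance(a.window3, b.window3) / len(a.window3)
    return min(1.0, (d5 + d3) / 2)


def group_full_length(
    segments: dict[str, str],
    w: int = DEFAULT_W,
    theta: float = DEFAULT_THETA,
    theta_ambig: float = DEFAULT_THETA_AMBIG,
    rdrp_segment_ids: set[str] | None = None,
) -> list[GenomeSet]:
    """Single-linkage grouping of oriented full-length segments.

    *segments* maps segment id -> oriented sequence.  Segments join one
    set when linked by terminal distance <= theta; near-misses in
    (theta, theta_ambig] cross-list the two sets in ``ambiguous_with``.
    """
    if not segments:
        raise ValueError("group_full_length requires at least one segment")
    rdrp_segment_ids = rdrp_segment_ids or set()
    ids = sorted(segments)
    profiles = {sid: TerminalProfile.from_sequence(sid, segments[sid], w) for sid in ids}

    parent = {sid: sid for sid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = terminal_distance(profiles[a], profiles[b])
            dist[(a, b)] = d
            if d <= theta:
                parent[find(a)] = find(b)

    clusters: dict[str, list[str]] = {}
    for sid in ids:
        clusters.setdefault(find(sid), []).append(sid)
    ordered = sorted(clusters.values(), key=lambda m: m[0])
    sets = []
    root_of: dict[str, int] = {}
    for n, members in enumerate(ordered):
        for sid in members:
            root_of[sid] = n
        pfm5, pfm3 = build_pfm({sid: segments[sid] for sid in members}, w)
        sets.append(
            GenomeSet(
                set_id=f"set_{n + 1:03d}",
                segment_ids=members,
                pfm5=pfm5,
                pfm3=pfm3,
                rdrp_segment_ids=sorted(set(members) & rdrp_segment_ids),
            )
        )
    for (a, b), d in dist.items():
        ia, ib = root_of[a], root_of[b]
        if ia == ib or not (theta < d <= theta_ambig):
            continue
        if sets[ib].set_id not in sets[ia].ambiguous_with:
            sets[ia].ambiguous_with.append(sets[ib].set_id)
        if sets[ia].set_id not in sets[ib].ambiguous_with:
            sets[ib].ambiguous_with.append(sets[ia].set_id)
    for gs in sets:
        gs.ambiguous_with.sort()
    return sets


def build_pfm(member_sequences: dict[str, str], w: int = DEFAULT_W) -> tuple[np.ndarray, np.ndarray]:
    """Position-frequency matrices (4 x w, rows ACGT) of the terminal windows.

    Column j is the base-frequency vector at window position j across
    members (pseudocount 0); each column sums to 1.
    """
    if not member_sequences:
        raise ValueError("build_pfm requires a non-empty set")
    pfm5 = np.zeros((4, w))
    pfm3 = np.zeros((4, w))
    for seq in member_sequences.values():
        prof = TerminalProfile.from_sequence("m", seq, w)
        for j, base in enumerate(prof.window5):
            if base in _BASES:
                pfm5[_BASES.index(base), j] += 1
        for j, base in enumerate(prof.window3):
            if base in _BASES:
                pfm3[_BASES.index(base), j] += 1
    pfm5 /= pfm5.sum(axis=0, keepdims=True)
    pfm3 /= pfm3.sum(axis=0, keepdims=True)
    return pfm5, pfm3


def pfm_to_tsv(pfm: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("base\t" + "\t".join(str(j) for j in range(pfm.shape[1])) + "\n")
        for i, base in enumerate(_BASES):
            fh.write(base + "\t" + "\t".join(f"{v:.4f}" for v in pfm[i]) + "\n")
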