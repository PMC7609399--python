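"""Terminus calling and full-length segment classification from pileups.

Libraries whose chemistry preserves genome-segment ends produce a
characteristic pileup: many reads begin (5') or end (3') at exactly the
true terminal coordinate, while at an arbitrary internal truncation the
extreme mapped coordinate is supported by few reads.  A terminus call at
a contig boundary therefore requires (a) at least ``min_support`` reads
starting/ending exactly at the extreme coordinate, (b) those reads being
at least ``min_fraction`` of the coverage at the adjacent base, and
(c) no alignment extending beyond it.  Contigs are first trimmed to
their covered span, so a passed 5' terminus sits at position 0 and a
passed 3' terminus at the (trimmed) contig length.

Reads flagged ambiguous by the mapper (placements tying across contigs —
typically reads from shared terminal windows) are excluded from terminus
support but still count toward coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from segvirome.assembly import Contig
from segvirome.mapping import ReadAlignment


@dataclass
class TerminusCall:
    contig_id: str
    side: str  # five_prime | three_prime
    position0: int
    support_reads: int
    support_fraction: float
    passed: bool


@dataclass
class SegmentCall:
    contig_id: str
    status: str  # full_length | partial
    termini: tuple[TerminusCall, TerminusCall]
    mean_coverage: float
    length: int
    sequence: str = ""
    trim_start: int = 0  # offset of the trimmed span on the original contig


@dataclass
class SegmentParams:
    min_support: int = 5
    min_fraction: float = 0.1


def depth_array(length: int, alignments: list[ReadAlignment]) -> np.ndarray:
    """Per-base read depth over a contig of *length* (all alignments)."""
    delta = np.zeros(length + 1, dtype=np.int64)
    for a in alignments:
        delta[a.start0] += 1
        delta[a.end0] -= 1
    return np.cumsum(delta[:-1])


def mean_coverage(contig: Contig | str, alignments: list[ReadAlignment]) -> float:
    """Sum of aligned bases divided by contig length."""
    seq = contig.sequence if isinstance(contig, Contig) else contig
    if len(seq) == 0:
        raise ValueError("contig length must be > 0")
    total = sum(a.end0 - a.start0 for a in alignments)
    return total / len(seq)


def call_termini(
    contig: Contig,
    alignments: list[ReadAlignment],
    min_support: int = 5,
    min_fraction: float = 0.1,
) -> tuple[TerminusCall, TerminusCall]:
    """Evaluate both ends of *contig*; positions refer to the covered span.

    With no alignments, both termini fail with support 0.
    """
    cid = contig.id
    if not alignments:
        return (
            TerminusCall(cid, "five_prime", 0, 0, 0.0, False),
            TerminusCall(cid, "three_prime", len(contig.sequence), 0, 0.0, False),
        )
    span_start = min(a.start0 for a in alignments)
    span_end = max(a.end0 for a in alignments)
    depth = depth_array(len(contig.sequence), alignments)
    unamb = [a for a in alignments if not a.ambiguous]

    s5 = sum(1 for a in unamb if a.start0 == span_start)
    cov5 = int(depth[span_start])
    f5 = s5 / cov5 if cov5 else 0.0
    t5 = TerminusCall(
        cid, "five_prime", span_start, s5, f5, s5 >= min_support and f5 >= min_fraction
    )

    s3 = sum(1 for a in unamb if a.end0 == span_end)
    cov3 = int(depth[span_end - 1])
    f3 = s3 / cov3 if cov3 else 0.0
    t3 = TerminusCall(
        cid, "three_prime", span_end, s3, f3, s3 >= min_support and f3 >= min_fraction
    )
    return t5, t3


def classify_segments(
    contigs: list[Contig],
    alignments: list[ReadAlignment],
    params: SegmentParams | None = None,
) -> list[SegmentCall]:
    """One SegmentCall per contig; full_length iff both termini pass.

    Each contig is trimmed to its covered span before terminus
    evaluation (assemblers may append unsupported bases), and reported
    positions/length/coverage refer to the trimmed span: a passed 5'
    terminus is position 0 and a passed 3' terminus equals the trimmed
    length.
    """
    params = params or SegmentParams()
    by_contig: dict[str, list[ReadAlignment]] = {c.id: [] for c in contigs}
    for a in alignments:
        if a.contig_id in by_contig:
            by_contig[a.contig_id].append(a)
    calls: list[SegmentCall] = []
    for contig in contigs:
        alns = by_contig[contig.id]
        t5, t3 = call_termini(contig, alns, params.min_support, params.min_fraction)
        if not alns:
            calls.append(
                SegmentCall(
                    contig.id, "partial", (t5, t3), 0.0, len(contig.sequence),
                    contig.sequence, 0,
                )
            )
            continue
        span_start, span_end = t5.position0, t3.position0
        trimmed = contig.sequence[span_start:span_end]
        length = span_end - span_start
        cov = sum(a.end0 - a.start0 for a in alns) / length
        # re-express terminus positions on the trimmed span
        t5 = TerminusCall(contig.id, "five_prime", 0, t5.support_reads, t5.support_fraction, t5.passed)
        t3 = TerminusCall(contig.id, "three_prime", length, t3.support_reads, t3.support_fraction, t3.passed)
        status = "full_length" if (t5.passed and t3.passed) else "partial"
        calls.append(SegmentCall(contig.id, status, (t5, t3), cov, length, trimmed, span_start))
    return calls


def segment_report(calls: list[SegmentCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "contig_id\tlength\tstatus\tterm5_pos\tterm5_support\t"
            "term3_pos\tterm3_support\tmean_coverage\n"
        )
        for c in calls:
            t5, t3 = c.termini
            fh.write(
                f"{c.contig_id}\t{c.length}\t{c.status}\t{t5.position0}\t"
                f"{t5.support_reads}\t{t3.position0}\t{t3.support_reads}\t"
                f"{c.mean_coverage:.1f}\n"
            )
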