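"""Quantitative community reports: read accounting, dominance, SSU profile.

These operations produce the paper-style quantitative surfaces of a
dsRNA/ssRNA virome survey: a per-library read-class accounting table
(trimmed / rRNA / major-virus / other), dominance calls (> 1000x mean
coverage on full-length segments), the fraction of RdRp-OTU coverage
held by the dominant segments, SSU rRNA class abundances, and OTU
richness per family label.
"""

from __future__ import annotations

from dataclasses import dataclass

from segvirome.mapping import ReadAlignment, map_reads
from segvirome.otus import RdRpOTU
from segvirome.segments import SegmentCall
from segvirome.seqio import ReadPair

DEFAULT_MIN_COV = 1000.0
DEFAULT_SSU_MIN_IDENTITY = 0.98


@dataclass
class CompositionReport:
    library: str
    n_trimmed: int
    n_rrna: int
    n_major_virus: int
    n_other: int

    def __post_init__(self) -> None:
        if self.n_rrna + self.n_major_virus + self.n_other != self.n_trimmed:
            raise ValueError("read classes must partition the trimmed reads")

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_trimmed if self.n_trimmed else 0.0

    @property
    def pct_rrna(self) -> float:
        return self._pct(self.n_rrna)

    @property
    def pct_major_virus(self) -> float:
        return self._pct(self.n_major_virus)

    @property
    def pct_other(self) -> float:
        return self._pct(self.n_other)

    def to_rows(self) -> list[tuple[str, int, float]]:
        return [
            ("Trimmed", self.n_trimmed, 100.0 if self.n_trimmed else 0.0),
            ("rRNA", self.n_rrna, self.pct_rrna),
            ("Major RNA viruses", self.n_major_virus, self.pct_major_virus),
            ("Others", self.n_other, self.pct_other),
        ]


@dataclass
class SSUProfile:
    abundances: dict[str, float]
    n_reads_used: int

    def __post_init__(self) -> None:
        if self.abundances and abs(sum(self.abundances.values()) - 1.0) > 1e-6:
            raise ValueError("class abundances must sum to 1")


def call_dominant(segments: list[SegmentCall], min_cov: float = DEFAULT_MIN_COV) -> set[str]:
    """Full-length segments with mean coverage strictly above ``min_cov``."""
    return {
        s.contig_id
        for s in segments
        if s.status == "full_length" and s.mean_coverage > min_cov
    }


def coverage_share(
    otus: list[RdRpOTU],
    centroid_coverage: dict[str, float],
    dominant_centroids: set[str],
) -> float | None:
    """Dominant OTUs' share of summed centroid coverage (None if total 0)."""
    total = sum(centroid_coverage.get(o.centroid_id, 0.0) for o in otus)
    if total == 0:
        return None
    dom = sum(
        centroid_coverage.get(o.centroid_id, 0.0)
        for o in otus
        if o.centroid_id in dominant_centroids
    )
    return dom / total


def compose_table(
    library: str,
    rrna_pairs: list[ReadPair],
    nonrrna_pairs: list[ReadPair],
    alignments: list[ReadAlignment],
    dominant_set_contigs: set[str],
) -> CompositionReport:
    """Assign every trimmed pair to exactly one class.

    Precedence: rRNA (either mate classified rRNA upstream), then major
    virus (either mate maps to a segment of a dominant genome set), then
    other — "other" is everything else, including unmapped pairs.
    """
    mapped_contigs: dict[str, set[str]] = {}
    for a in alignments:
        base = a.read_id.rsplit("/", 1)[0]
        mapped_contigs.setdefault(base, set()).add(a.contig_id)
    n_major = sum(
        1
        for pair in nonrrna_pairs
        if mapped_contigs.get(pair.read_id, set()) & dominant_set_contigs
    )
    n_trimmed = len(rrna_pairs) + len(nonrrna_pairs)
    return CompositionReport(
        library=library,
        n_trimmed=n_trimmed,
        n_rrna=len(rrna_pairs),
        n_major_virus=n_major,
        n_other=n_trimmed - len(rrna_pairs) - n_major,
    )


def profile_ssu(
    reads: list[tuple[str, str]],
    ssu_reference: dict[str, str],
    class_labels: dict[str, str],
    min_identity: float = DEFAULT_SSU_MIN_IDENTITY,
) -> SSUProfile:
    """SSU class abundances from best-identity read assignment.

    Each read is placed end-to-end (ungapped, either strand) on its
    best reference; it is assigned iff identity over the aligned span is
    >= ``min_identity``.  Abundances are computed over assigned reads.
    """
    if not ssu_reference:
        raise ValueError("SSU reference is empty")
    max_mm_frac = 1.0 - min_identity
    alignments, _ = map_reads(reads, ssu_reference, max_mismatch_frac=max_mm_frac)
    counts: dict[str, int] = {}
    n_used = 0
    for a in alignments:
        label = class_labels.get(a.contig_id, a.contig_id)
        counts[label] = counts.get(label, 0) + 1
        n_used += 1
    abundances = {cls: n / n_used for cls, n in sorted(counts.items())} if n_used else {}
    return SSUProfile(abundances=abundances, n_reads_used=n_used)


def richness_by_family(otus: list[RdRpOTU]) -> dict[str, int]:
    """OTU counts per family label; unlabeled OTUs bin as 'unclassified'."""
    out: dict[str, int] = {}
    for otu in otus:
        label = otu.family_label or "unclassified"
        out[label] = out.get(label, 0) + 1
    return dict(sorted(out.items()))


def composition_to_tsv(report: CompositionReport, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"class\tn_read_pairs\tpercent\t# library={report.library}\n")
        for name, n, pct in report.to_rows():
            fh.write(f"{name}\t{n}\t{pct:.1f}\n")
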