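"""RdRp detection by six-frame translated search and 90 %-identity OTUs.

RNA-dependent RNA polymerase is the one gene shared by all non-retro RNA
viruses, so RdRp-bearing nucleotide sequences define the operational
taxonomic units of an RNA virome.  Detection here is a translated
(BLASTX-style) search: every reading frame of the query is locally
aligned (affine gaps, BLOSUM62) against a bundled labelled protein
panel, and an e-value is estimated with the extreme-value formula
E = K*m*n*exp(-lambda*S) using the standard gapped BLOSUM62 constants
(K = 0.041, lambda = 0.267) and the panel size as database size.
Externally computed BLAST tabular results can be imported instead.

OTUs follow the common centroid-greedy strategy: sequences longer than
``min_length`` are sorted by length, the longest seeds a cluster, and
each subsequent sequence joins the first centroid it matches at
``identity_threshold`` global identity, else seeds a new one.  Identity
counts matches over alignment columns with terminal gaps excluded and
internal gaps included.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from segvirome.seqio import revcomp

logger = logging.getLogger(__name__)

GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041
DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_IDENTITY_THRESHOLD = 0.90
DEFAULT_MIN_LENGTH = 1500


@dataclass
class PanelHit:
    query_id: str
    frame: int  # +1..+3, -1..-3
    panel_id: str
    family_label: str
    score: float
    evalue_estimate: float
    query_region0: tuple[int, int]  # half-open nt interval, plus strand


@dataclass
class RdRpOTU:
    centroid_id: str
    member_ids: list[str]
    family_label: str = "unclassified"
    centroid_length: int = 0
    is_dominant: bool = False


def _aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11
    aln.extend_gap_score = -1
    return aln


def _shared_words(a: str, b_words: set[str], w: int = 5) -> bool:
    return any(a[i : i + w] in b_words for i in range(len(a) - w + 1))


def six_frames(query: str) -> list[tuple[int, str]]:
    """(frame, translation) for frames +1..+3 and -1..-3."""
    out = []
    rc = revcomp(query)
    for off in range(3):
        for sign, seq in ((1, query), (-1, rc)):
            frame = sign * (off + 1)
            sub = seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            out.append((frame, str(Seq(sub).translate())))
    return out


def translated_search(
    query: str,
    panel: dict[str, str],
    min_score: float = 50.0,
    family_labels: dict[str, str] | None = None,
    query_id: str = "query",
) -> list[PanelHit]:
    """Local-align all six frames of *query* against every panel protein.

    Hits with score >= ``min_score`` are returned sorted by descending
    score (ties: lowest e-value, then panel id).  Frames consisting only
    of stop codons are skipped silently.
    """
    if len(query) < 60:
        raise ValueError("query must be >= 60 nt")
    if not panel:
        raise ValueError("panel is empty")
    family_labels = family_labels or {}
    aligner = _aligner()
    db_residues = sum(len(p) for p in panel.values())
    words: dict[str, set[str]] = {
        pid: {p[i : i + 5] for i in range(len(p) - 4)} for pid, p in panel.items()
    }
    L = len(query)
    hits: list[PanelHit] = []
    for frame, trans in six_frames(query):
        if not trans.replace("*", ""):
            continue
        m = len(trans)
        for pid, prot in panel.items():
            if not _shared_words(trans, words[pid]):
                continue
            result = aligner.align(trans, prot)
            if len(result) == 0:
                continue
            best = result[0]
            score = float(best.score)
            if score < min_score:
                continue
            qa_start = int(best.aligned[0][0][0])
            qa_end = int(best.aligned[0][-1][1])
            off = abs(frame) - 1
            if frame > 0:
                region = (off + 3 * qa_start, off + 3 * qa_end)
            else:
                region = (L - off - 3 * qa_end, L - off - 3 * qa_start)
            evalue = GAPPED_K * m * db_residues * math.exp(-GAPPED_LAMBDA * score)
            hits.append(
                PanelHit(
                    query_id=query_id,
                    frame=frame,
                    panel_id=pid,
                    family_label=family_labels.get(pid, pid),
                    score=score,
                    evalue_estimate=evalue,
                    query_region0=region,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.evalue_estimate, h.panel_id, h.frame))
    return hits


_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def global_identity(a: str, b: str, reject_below: float = 0.5) -> float:
    """Global-alignment identity: matches / columns, terminal gaps excluded.

    ``reject_below`` bounds the edit-distance band searched; pairs more
    distant than that return 0.0 (they cannot reach any threshold of
    interest).
    """
    if not a or not b:
        return 0.0
    k = max(1, int((1.0 - reject_below) * max(len(a), len(b))))
    res = edlib.align(a, b, mode="NW", task="path", k=k)
    if res["editDistance"] == -1:
        return 0.0
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(res["cigar"])]
    # trim terminal gap runs on both sides
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    columns = sum(n for n, _ in ops)
    matches = sum(n for n, op in ops if op == "=")
    return matches / columns if columns else 0.0


def greedy_cluster(
    sequences: dict[str, str],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[RdRpOTU]:
    """Centroid-greedy clustering of RdRp-bearing nucleotide sequences.

    Sequences of length <= ``min_length`` are dropped (the length rule is
    strict).  Input order does not matter: processing order is length
    descending, ties lexicographic by id.
    """
    kept = sorted(
        ((sid, seq) for sid, seq in sequences.items() if len(seq) > min_length),
        key=lambda item: (-len(item[1]), item[0]),
    )
    otus: list[RdRpOTU] = []
    for sid, seq in kept:
        placed = False
        for otu in otus:
            ident = global_identity(sequences[otu.centroid_id], seq)
            if ident >= identity_threshold:
                otu.member_ids.append(sid)
                placed = True
                break
        if not placed:
            otus.append(RdRpOTU(centroid_id=sid, member_ids=[sid], centroid_length=len(seq)))
    return otus


def import_blast_tab(
    path: str | Path,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    family_labels: dict[str, str] | None = None,
) -> list[PanelHit]:
    """Import standard 12-column BLAST tabular output.

    Rows with e-value <= ``evalue_max`` are converted; the rest are
    dropped with a logged count.  Malformed rows raise ``ValueError``
    with the line number.
    """
    family_labels = family_labels or {}
    hits: list[PanelHit] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"line {lineno}: expected 12 columns, got {len(parts)}")
            try:
                qid, sid = parts[0], parts[1]
                qstart, qend = int(parts[6]), int(parts[7])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed row ({exc})") from exc
            if evalue > evalue_max:
                dropped += 1
                continue
            if qstart <= qend:
                region = (qstart - 1, qend)
                frame = (qstart - 1) % 3 + 1
            else:
                region = (qend - 1, qstart)
                frame = -((qend - 1) % 3 + 1)
            hits.append(
                PanelHit(
                    query_id=qid,
                    frame=frame,
                    panel_id=sid,
                    family_label=family_labels.get(sid, sid),
                    score=bitscore,
                    evalue_estimate=evalue,
                    query_region0=region,
                )
            )
    if dropped:
        logger.info("import_blast_tab: dropped %d rows above e-value %.1e", dropped, evalue_max)
    return hits


def otu_table(otus: list[RdRpOTU], best_hits: dict[str, PanelHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("centroid_id\tn_members\tlength\tfamily_label\tbest_score\tevalue_estimate\n")
        for otu in otus:
            hit = best_hits.get(otu.centroid_id)
            score = f"{hit.score:.1f}" if hit else "NA"
            ev = f"{hit.evalue_estimate:.3g}" if hit else "NA"
            fh.write(
                f"{otu.centroid_id}\t{len(otu.member_ids)}\t{otu.centroid_length}\t"
                f"{otu.family_label}\t{score}\t{ev}\n"
            )
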