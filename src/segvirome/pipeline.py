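"""End-to-end orchestration: simulate -> filter -> assemble -> map ->
segments -> OTUs -> genome sets -> reports.

`run_pipeline` drives the whole analysis on a synthetic community (or,
via the stage functions it calls, on externally supplied reads/contigs)
and returns every intermediate surface the reports are built from, so
callers can interrogate any stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from segvirome import panels
from segvirome.assembly import Contig, assemble
from segvirome.community import CommunitySpec, build_genomes, simulate_library
from segvirome.genome_sets import GenomeSet, group_full_length, orient_segment
from segvirome.mapping import ContigIndex, ReadAlignment, map_reads
from segvirome.otus import (
    DEFAULT_EVALUE_MAX,
    PanelHit,
    RdRpOTU,
    greedy_cluster,
    translated_search,
)
from segvirome.reports import (
    CompositionReport,
    SSUProfile,
    call_dominant,
    compose_table,
    coverage_share,
    profile_ssu,
    richness_by_family,
)
from segvirome.rrna import build_index, filter_library
from segvirome.segments import SegmentCall, SegmentParams, classify_segments, depth_array
from segvirome.seqio import ReadPair, revcomp

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    k: int = 15
    tau: float = 0.2
    min_overlap: int = 50
    seed_k: int = 15
    max_mismatch_frac: float = 0.05
    min_support: int = 5
    min_fraction: float = 0.1
    w: int = 30
    theta: float = 0.2
    theta_ambig: float = 0.35
    identity_threshold: float = 0.90
    min_length: int = 1500
    min_cov: float = 1000.0
    min_identity: float = 0.98
    evalue_max: float = DEFAULT_EVALUE_MAX
    min_rdrp_score: float = 50.0


@dataclass
class RdRpRegion:
    """The clustered RdRp nucleotide span of one contig."""

    centroid_id: str
    contig_id: str
    sequence: str
    # half-open interval on the original (untrimmed) contig plus strand
    contig_interval: tuple[int, int]
    best_hit: PanelHit
    strand: str = "+"  # coding strand relative to the contig as assembled


@dataclass
class PipelineResult:
    spec: CommunitySpec
    genomes: list[tuple[str, list[str]]]
    contigs: list[Contig]
    segment_calls: list[SegmentCall]
    dominant_contigs: set[str]
    dominant_set_contigs: set[str]
    otus: list[RdRpOTU]
    rdrp_regions: dict[str, RdRpRegion]
    genome_sets: list[GenomeSet]
    composition: dict[str, CompositionReport]
    centroid_coverage: dict[str, dict[str, float]]  # library -> centroid -> x
    ssu_profile: SSUProfile | None
    truth: dict[str, pd.DataFrame]
    filter_counts: dict[str, dict[str, int]]


def _flatten(pairs: list[ReadPair]) -> list[tuple[str, str]]:
    out = []
    for p in pairs:
        out.append((p.read_id + "/1", p.seq1))
        out.append((p.read_id + "/2", p.seq2))
    return out


def find_rdrp_regions(
    calls: list[SegmentCall],
    params: PipelineParams,
) -> dict[str, RdRpRegion]:
    """Best-hit RdRp region per contig, on the coding strand.

    The clustered span is the union of the best translated-search hit
    region with the in-frame stop-free run containing it, mapped back to
    original contig coordinates.
    """
    prot_panel, families = panels.load_rdrp_panel()
    regions: dict[str, RdRpRegion] = {}
    for call in calls:
        seq = call.sequence
        if len(seq) < 60:
            continue
        hits = translated_search(
            seq, prot_panel, params.min_rdrp_score, families, query_id=call.contig_id
        )
        hits = [h for h in hits if h.evalue_estimate <= params.evalue_max]
        if not hits:
            continue
        oriented = orient_segment(seq, hits)
        if oriented != seq:
            # re-express the best hit on the oriented strand
            hits = translated_search(
                oriented, prot_panel, params.min_rdrp_score, families, query_id=call.contig_id
            )
            hits = [h for h in hits if h.evalue_estimate <= params.evalue_max]
            if not hits:
                continue
        best = hits[0]
        start, end = _orf_union_span(oriented, best)
        flipped = oriented != seq
        L = len(seq)
        if flipped:
            c_start, c_end = L - end, L - start
        else:
            c_start, c_end = start, end
        regions[call.contig_id] = RdRpRegion(
            centroid_id=f"{call.contig_id}|rdrp",
            contig_id=call.contig_id,
            sequence=oriented[start:end],
            contig_interval=(call.trim_start + c_start, call.trim_start + c_end),
            best_hit=best,
            strand="-" if flipped else "+",
        )
    return regions


def _orf_union_span(seq: str, hit: PanelHit) -> tuple[int, int]:
    """Union of the hit region and its surrounding in-frame stop-free run."""
    start, end = hit.query_region0
    frame_off = start % 3
    stops = {"TAA", "TAG", "TGA"}
    mid = start + 3 * (((end - start) // 3) // 2)
    lo = mid
    while lo - 3 >= frame_off:
        if seq[lo - 3 : lo] in stops:
            break
        lo -= 3
    hi = mid
    while hi + 3 <= len(seq):
        codon = seq[hi : hi + 3]
        hi += 3
        if codon in stops:
            break
    return min(start, lo), max(end, hi)


def region_coverage(
    regions: dict[str, RdRpRegion],
    contigs: dict[str, str],
    alignments: list[ReadAlignment],
) -> dict[str, float]:
    """Mean per-base depth over each RdRp region (centroid id keyed)."""
    by_contig: dict[str, list[ReadAlignment]] = {}
    for a in alignments:
        by_contig.setdefault(a.contig_id, []).append(a)
    out: dict[str, float] = {}
    for region in regions.values():
        alns = by_contig.get(region.contig_id, [])
        depth = depth_array(len(contigs[region.contig_id]), alns)
        s, e = region.contig_interval
        out[region.centroid_id] = float(depth[s:e].mean()) if e > s else 0.0
    return out


def run_pipeline(
    spec: CommunitySpec,
    seed: int | None = None,
    params: PipelineParams | None = None,
    with_ssrna: bool = True,
) -> PipelineResult:
    params = params or PipelineParams()
    root = spec.seed if seed is None else seed
    genomes = build_genomes(spec, root)

    ssu_seqs, ssu_classes = panels.load_ssu_panel()
    rrna_index = build_index(ssu_seqs, params.k, taxonomy=ssu_classes)

    # --- dsRNA library ---------------------------------------------------
    ds_pairs, ds_truth = simulate_library(genomes, spec, "dsRNA", root)
    ds_rrna, ds_non, ds_counts = filter_library(ds_pairs, rrna_index, params.tau)
    logger.info("dsRNA: %s", ds_counts)

    contigs = assemble(ds_non, params.min_overlap, params.max_mismatch_frac)
    contig_seqs = {c.id: c.sequence for c in contigs}
    index = ContigIndex(contig_seqs, params.seed_k)
    ds_alns, _ = map_reads(
        _flatten(ds_non), contig_seqs, params.seed_k, params.max_mismatch_frac, index
    )

    seg_params = SegmentParams(params.min_support, params.min_fraction)
    calls = classify_segments(contigs, ds_alns, seg_params)
    dominant = call_dominant(calls, params.min_cov)

    regions = find_rdrp_regions(calls, params)
    otu_input = {r.centroid_id: r.sequence for r in regions.values()}
    otus = greedy_cluster(otu_input, params.identity_threshold, params.min_length)
    for otu in otus:
        region = regions[otu.centroid_id.rsplit("|", 1)[0]]
        otu.family_label = region.best_hit.family_label
        otu.is_dominant = region.contig_id in dominant

    # --- genome sets over full-length segments ---------------------------
    full = [c for c in calls if c.status == "full_length"]
    oriented: dict[str, str] = {}
    rdrp_ids: set[str] = set()
    for call in full:
        if call.contig_id in regions:
            region = regions[call.contig_id]
            oriented[call.contig_id] = (
                revcomp(call.sequence) if region.strand == "-" else call.sequence
            )
            rdrp_ids.add(call.contig_id)
        else:
            oriented[call.contig_id] = orient_segment(call.sequence, None)
    genome_sets = (
        group_full_length(oriented, params.w, params.theta, params.theta_ambig, rdrp_ids)
        if oriented
        else []
    )
    dominant_set_contigs = set(dominant)
    for gs in genome_sets:
        if set(gs.segment_ids) & dominant:
            dominant_set_contigs.update(gs.segment_ids)

    composition = {
        "dsRNA": compose_table("dsRNA", ds_rrna, ds_non, ds_alns, dominant_set_contigs)
    }
    centroid_cov = {"dsRNA": region_coverage(regions, contig_seqs, ds_alns)}
    truth = {"dsRNA": ds_truth}
    filter_counts = {"dsRNA": ds_counts}
    ssu_profile = None

    # --- ssRNA library ----------------------------------------------------
    if with_ssrna:
        ss_pairs, ss_truth = simulate_library(genomes, spec, "ssRNA", root)
        ss_rrna, ss_non, ss_counts = filter_library(ss_pairs, rrna_index, params.tau)
        logger.info("ssRNA: %s", ss_counts)
        ss_alns, _ = map_reads(
            _flatten(ss_non), contig_seqs, params.seed_k, params.max_mismatch_frac, index
        )
        composition["ssRNA"] = compose_table(
            "ssRNA", ss_rrna, ss_non, ss_alns, dominant_set_contigs
        )
        centroid_cov["ssRNA"] = region_coverage(regions, contig_seqs, ss_alns)
        ssu_profile = profile_ssu(
            _flatten(ss_rrna), ssu_seqs, ssu_classes, params.min_identity
        )
        truth["ssRNA"] = ss_truth
        filter_counts["ssRNA"] = ss_counts

    return PipelineResult(
        spec=spec,
        genomes=genomes,
        contigs=contigs,
        segment_calls=calls,
        dominant_contigs=dominant,
        dominant_set_contigs=dominant_set_contigs,
        otus=otus,
        rdrp_regions=regions,
        genome_sets=genome_sets,
        composition=composition,
        centroid_coverage=centroid_cov,
        ssu_profile=ssu_profile,
        truth=truth,
        filter_counts=filter_counts,
    )


def dominant_coverage_share(result: PipelineResult, library: str) -> float | None:
    dominant_centroids = {o.centroid_id for o in result.otus if o.is_dominant}
    return coverage_share(
        result.otus, result.centroid_coverage[library], dominant_centroids
    )


def otu_richness(result: PipelineResult) -> dict[str, int]:
    return richness_by_family(result.otus)
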