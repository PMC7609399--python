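"""Greedy overlap assembly and seed-based ungapped mapping."""

import numpy as np
import pytest

from segvirome.assembly import assemble
from segvirome.community import simulate_library
from segvirome.mapping import brute_force_map, import_sam, map_reads
from segvirome.segments import SegmentParams, classify_segments
from segvirome.seqio import revcomp
from tests.conftest import make_spec, make_virus


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_exact_overlap_merges_two_reads():
    rng = np.random.default_rng(0)
    a = _random_seq(rng, 100)
    b = a[-50:] + _random_seq(rng, 50)
    contigs = assemble([("r1", a), ("r2", b)], min_overlap=50)
    assert len(contigs) == 1
    assert len(contigs[0].sequence) == 150
    assert contigs[0].sequence in (a + b[50:], revcomp(a + b[50:]))


def test_below_threshold_overlap_does_not_merge():
    rng = np.random.default_rng(1)
    a = _random_seq(rng, 100)
    b = a[-40:] + _random_seq(rng, 60)
    contigs = assemble([("r1", a), ("r2", b)], min_overlap=50)
    assert len(contigs) == 2


def test_error_free_tiling_reconstructs_segment():
    rng = np.random.default_rng(2)
    segment = _random_seq(rng, 2000)
    reads = [(f"r{i:04d}", segment[s : s + 100]) for i, s in enumerate(range(0, 1901, 20))]
    contigs = assemble(reads, min_overlap=50)
    assert len(contigs) == 1
    assert contigs[0].sequence in (segment, revcomp(segment))


def test_shared_termini_do_not_chimerise():
    """Segments sharing only a 30 nt motif never merge at min_overlap=40."""
    rng = np.random.default_rng(3)
    motif5, motif3 = _random_seq(rng, 30), _random_seq(rng, 30)
    seg_a = motif5 + _random_seq(rng, 600) + motif3
    seg_b = motif5 + _random_seq(rng, 500) + motif3
    reads = []
    for tag, seg in (("a", seg_a), ("b", seg_b)):
        for i, s in enumerate(range(0, len(seg) - 99, 15)):
            reads.append((f"{tag}{i:04d}", seg[s : s + 100]))
        reads.append((f"{tag}_end", seg[-100:]))
    contigs = assemble(reads, min_overlap=40)
    assert len(contigs) == 2
    lengths = sorted(len(c.sequence) for c in contigs)
    assert lengths == [len(seg_b), len(seg_a)]


def test_map_prefix_read():
    rng = np.random.default_rng(4)
    contig = _random_seq(rng, 500)
    alns, unmapped = map_reads([("p", contig[:120])], {"c": contig})
    assert not unmapped
    a = alns[0]
    assert (a.contig_id, a.start0, a.end0, a.strand, a.n_mismatches) == ("c", 0, 120, "+", 0)


def test_map_reverse_complement_infix_matches_bruteforce():
    rng = np.random.default_rng(5)
    contig = _random_seq(rng, 500)
    read = revcomp(contig[200:320])
    alns, _ = map_reads([("r", read)], {"c": contig})
    a = alns[0]
    oracle = brute_force_map(read, {"c": contig})
    assert (a.contig_id, a.start0, a.strand, a.n_mismatches) == oracle[:4]
    assert (a.start0, a.end0, a.strand) == (200, 320, "-")


def test_mapper_equals_exhaustive_scan_oracle():
    """Best placements match an all-position, both-strand scan."""
    rng = np.random.default_rng(6)
    contigs = {f"c{i}": _random_seq(rng, 400) for i in range(5)}
    reads = []
    for i in range(50):
        cid = f"c{rng.integers(5)}"
        start = int(rng.integers(0, 300))
        read = list(contigs[cid][start : start + 100])
        for _ in range(int(rng.integers(0, 4))):  # up to 3 mutations
            pos = int(rng.integers(100))
            read[pos] = "ACGT".replace(read[pos], "")[rng.integers(3)]
        seq = "".join(read)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append((f"r{i}", seq))
    alns, unmapped = map_reads(reads, contigs)
    by_id = {a.read_id: a for a in alns}
    for read_id, seq in reads:
        oracle = brute_force_map(seq, contigs)
        if oracle is None:
            assert read_id in unmapped
        else:
            a = by_id[read_id]
            assert (a.contig_id, a.start0, a.strand, a.n_mismatches) == oracle


def test_synthetic_reads_map_back_to_truth(small_spec, small_genomes):
    """Error-free viral reads land inside their true fragment intervals."""
    spec = make_spec(small_spec.viruses, n_ds=400, substitution_error_rate=0.0, seed=31)
    pairs, truth = simulate_library(small_genomes, spec, "dsRNA", 31)
    segs = {
        f"{name}/seg{i + 1}": s
        for name, segs_ in small_genomes
        for i, s in enumerate(segs_)
    }
    viral = truth[truth["class"] == "major_virus"].set_index("read_id")
    reads = []
    for p in pairs:
        if p.read_id in viral.index:
            reads.append((p.read_id + "/1", p.seq1))
            reads.append((p.read_id + "/2", p.seq2))
    alns, unmapped = map_reads(reads, segs)
    assert not unmapped
    for a in alns:
        rec = viral.loc[a.read_id.rsplit("/", 1)[0]]
        assert a.contig_id == rec["source"]
        assert rec["start0"] <= a.start0 and a.end0 <= rec["end0_halfopen"]


def test_sam_import_gives_same_segment_calls(tmp_path):
    """Segment calls agree between built-in alignments and imported SAM."""
    from segvirome.assembly import Contig

    rng = np.random.default_rng(8)
    contig = _random_seq(rng, 600)
    reads = [(f"r{i:03d}", contig[s : s + 100]) for i, s in enumerate(range(0, 501, 10))]
    reads += [("rc1", revcomp(contig[250:350]))]
    alns, _ = map_reads(reads, {"seg": contig})
    sam = tmp_path / "alns.sam"
    with open(sam, "w") as fh:
        fh.write("@HD\tVN:1.6\n@SQ\tSN:seg\tLN:600\n")
        for a in alns:
            flag = 16 if a.strand == "-" else 0
            fh.write(
                f"{a.read_id}\t{flag}\tseg\t{a.start0 + 1}\t60\t{a.end0 - a.start0}M\t"
                f"*\t0\t0\t*\t*\tNM:i:{a.n_mismatches}\n"
            )
    imported = import_sam(sam)
    contigs = [Contig("seg", contig)]
    params = SegmentParams(min_support=1, min_fraction=0.0)
    built = classify_segments(contigs, alns, params)
    ext = classify_segments(contigs, imported, params)
    assert [(c.status, c.length, c.mean_coverage) for c in built] == [
        (c.status, c.length, c.mean_coverage) for c in ext
    ]


def test_sam_import_skips_indel_records(tmp_path):
    sam = tmp_path / "x.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:seg\tLN:600\n"
        "ok\t0\tseg\t1\t60\t100M\t*\t0\t0\t*\t*\tNM:i:0\n"
        "indel\t0\tseg\t1\t60\t50M2I48M\t*\t0\t0\t*\t*\tNM:i:2\n"
        "clip\t16\tseg\t10\t60\t10S90M\t*\t0\t0\t*\t*\tNM:i:0\n"
    )
    imported = import_sam(sam)
    assert [a.read_id for a in imported] == ["ok"]
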