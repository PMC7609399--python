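"""Translated RdRp search, greedy identity clustering, BLAST import."""

import numpy as np
import pytest

from segvirome.community import back_translate, rdrp_lineage_set
from segvirome.otus import (
    global_identity,
    greedy_cluster,
    import_blast_tab,
    translated_search,
)
from segvirome.panels import load_rdrp_panel
from segvirome.seqio import revcomp

PANEL, FAMILIES = load_rdrp_panel()


def _orf_query(panel_id="RdRp_Partitiviridae_1", seed=0, pad=50):
    rng = np.random.default_rng(seed)
    orf = back_translate(PANEL[panel_id], rng)
    flank = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    left = flank(pad - pad % 3)  # keep the ORF in frame +1
    return left + orf + flank(pad), len(left), len(orf)


def test_exact_backtranslation_is_top_hit_in_frame_plus_one():
    query, left, orf_len = _orf_query()
    hits = translated_search(query, PANEL, family_labels=FAMILIES)
    top = hits[0]
    assert top.panel_id == "RdRp_Partitiviridae_1"
    assert top.family_label == "Partitiviridae"
    assert top.frame == 1
    assert top.evalue_estimate < 1e-5
    start, end = top.query_region0
    assert (end - start) % 3 == 0
    assert start >= left and end <= left + orf_len


def test_reverse_complement_hits_negative_frame():
    query, left, orf_len = _orf_query(seed=1)
    fwd = translated_search(query, PANEL)[0]
    rev = translated_search(revcomp(query), PANEL)[0]
    assert rev.panel_id == fwd.panel_id
    assert rev.frame < 0
    L = len(query)
    # region maps back to the same plus-strand interval of the original
    assert (L - rev.query_region0[1], L - rev.query_region0[0]) == fwd.query_region0


def test_short_query_rejected():
    with pytest.raises(ValueError, match="60"):
        translated_search("ACGT" * 10, PANEL)


def test_family_recovery_under_divergence():
    """10 % amino-acid divergence still labels the source family."""
    seqs, _, family_of = rdrp_lineage_set(
        n_lineages=30, n_partiti=10, variants_per_lineage=0, seed=17
    )
    n_correct = 0
    for lid, seq in seqs.items():
        hits = translated_search(seq, PANEL, family_labels=FAMILIES)
        if hits and hits[0].family_label == family_of[lid]:
            n_correct += 1
    assert n_correct >= 29


def _random_seq(rng, n=2000):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_cluster_identical_sequences():
    rng = np.random.default_rng(2)
    s = _random_seq(rng)
    otus = greedy_cluster({"a": s, "b": s})
    assert len(otus) == 1 and sorted(otus[0].member_ids) == ["a", "b"]


def test_cluster_unrelated_sequences():
    rng = np.random.default_rng(3)
    otus = greedy_cluster({"a": _random_seq(rng), "b": _random_seq(rng)})
    assert len(otus) == 2


def test_length_threshold_is_strict():
    rng = np.random.default_rng(4)
    seqs = {"len1500": _random_seq(rng, 1500), "len1501": _random_seq(rng, 1501)}
    otus = greedy_cluster(seqs)
    assert [o.centroid_id for o in otus] == ["len1501"]


def _brute_force_single_linkage(seqs: dict[str, str], threshold: float) -> list[set[str]]:
    ids = sorted(seqs)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if global_identity(seqs[a], seqs[b]) >= threshold:
                parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda g: sorted(g)[0])


def test_planted_clusters_match_bruteforce_oracle():
    """k well-separated lineages with close variants give exactly k OTUs."""
    seqs, lineage_of, _ = rdrp_lineage_set(
        n_lineages=5, n_partiti=2, variants_per_lineage=2, seed=23
    )
    otus = greedy_cluster(seqs)
    assert len(otus) == 5
    assert all(len(o.member_ids) == 3 for o in otus)
    greedy_partition = sorted(
        (set(o.member_ids) for o in otus), key=lambda g: sorted(g)[0]
    )
    assert greedy_partition == _brute_force_single_linkage(seqs, 0.90)
    # recovered clusters coincide with planted lineages
    for otu in otus:
        assert len({lineage_of[m] for m in otu.member_ids}) == 1


def test_cluster_order_independence():
    seqs, _, _ = rdrp_lineage_set(n_lineages=4, n_partiti=2, variants_per_lineage=2, seed=29)
    otus1 = greedy_cluster(dict(seqs))
    otus2 = greedy_cluster(dict(reversed(list(seqs.items()))))
    part1 = sorted(sorted(o.member_ids) for o in otus1)
    part2 = sorted(sorted(o.member_ids) for o in otus2)
    assert part1 == part2


def test_centroid_pairwise_identities_below_threshold():
    seqs, _, _ = rdrp_lineage_set(n_lineages=6, n_partiti=3, variants_per_lineage=1, seed=31)
    otus = greedy_cluster(seqs)
    cents = [o.centroid_id for o in otus]
    for i, a in enumerate(cents):
        for b in cents[i + 1 :]:
            assert global_identity(seqs[a], seqs[b], reject_below=0.0) < 0.90


def test_every_long_sequence_in_exactly_one_otu():
    seqs, _, _ = rdrp_lineage_set(n_lineages=4, n_partiti=1, variants_per_lineage=2, seed=37)
    otus = greedy_cluster(seqs)
    members = [m for o in otus for m in o.member_ids]
    assert sorted(members) == sorted(seqs)


BLAST_ROW = "{q}\t{s}\t95.0\t500\t25\t0\t1\t1500\t1\t500\t{e}\t800"


def test_blast_import_empty_and_threshold(tmp_path):
    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    assert import_blast_tab(empty) == []

    tab = tmp_path / "hits.tsv"
    rows = [
        BLAST_ROW.format(q="q1", s="p1", e="1e-30"),
        BLAST_ROW.format(q="q2", s="p2", e="1e-4"),  # above threshold: dropped
        BLAST_ROW.format(q="q3", s="p3", e="1e-6"),
        BLAST_ROW.format(q="q4", s="p4", e="2e-5"),  # dropped
        BLAST_ROW.format(q="q5", s="p5", e="1e-5"),  # boundary: kept
    ]
    tab.write_text("\n".join(rows) + "\n")
    hits = import_blast_tab(tab)
    assert [h.query_id for h in hits] == ["q1", "q3", "q5"]
    assert hits[0].query_region0 == (0, 1500)


def test_blast_import_malformed_row(tmp_path):
    tab = tmp_path / "bad.tsv"
    tab.write_text(BLAST_ROW.format(q="q1", s="p1", e="1e-30") + "\nnot\ta\trow\n")
    with pytest.raises(ValueError, match="line 2"):
        import_blast_tab(tab)
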