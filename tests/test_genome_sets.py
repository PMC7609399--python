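"""Terminal-sequence genome-set grouping, orientation, PFMs."""

import numpy as np
import pytest

from segvirome.community import back_translate, build_genomes, lichen_community_spec
from segvirome.genome_sets import (
    TerminalProfile,
    build_pfm,
    edit_distance,
    group_full_length,
    orient_segment,
    terminal_distance,
)
from segvirome.otus import PanelHit, translated_search
from segvirome.panels import load_rdrp_panel
from segvirome.seqio import revcomp
from tests.conftest import make_spec, make_virus

PANEL, FAMILIES = load_rdrp_panel()


def _hit(frame):
    return PanelHit("q", frame, "p", "fam", 100.0, 1e-20, (0, 300))


def test_orientation_by_hit_frame():
    seq = "ATGGCCATTGTAATGGGCCGCTGAAAGGGTGCCCGA" * 5
    assert orient_segment(seq, [_hit(1)]) == seq
    assert orient_segment(seq, [_hit(-2)]) == revcomp(seq)


def test_orientation_involution_on_planted_orf():
    """A segment and its reverse complement orient to the same strand."""
    rng = np.random.default_rng(0)
    orf = back_translate("M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 150)), rng)
    seq = "".join(rng.choice(list("ACGT"), 30)) + orf + "".join(rng.choice(list("ACGT"), 30))
    assert orient_segment(seq, None) == seq
    assert orient_segment(revcomp(seq), None) == seq


def test_terminal_distance_basic_cases():
    a = TerminalProfile("a", "A" * 30, "C" * 30)
    assert terminal_distance(a, a) == 0.0
    b = TerminalProfile("b", "C" * 30, "A" * 30)  # maximally distant
    assert terminal_distance(a, b) == 1.0
    w5 = "A" * 27 + "CGT"
    w3 = "C" * 27 + "GTA"
    c = TerminalProfile("c", w5, w3)  # 3 substitutions per side
    assert terminal_distance(a, c) == pytest.approx(0.1)
    assert terminal_distance(a, c) == terminal_distance(c, a)


def _dp_edit_distance(a: str, b: str) -> int:
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]


def test_edit_distance_matches_dp_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 40))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 40))))
        assert edit_distance(a, b) == _dp_edit_distance(a, b)


def test_single_segment_forms_singleton_set():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    (gs,) = group_full_length({"s1": seq})
    assert gs.segment_ids == ["s1"]
    assert not gs.ambiguous


def _exhaustive_partition_oracle(segments, w, theta):
    """Transitive closure over all pairwise distances (n small)."""
    ids = sorted(segments)
    profs = {i: TerminalProfile.from_sequence(i, segments[i], w) for i in ids}
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if terminal_distance(profs[a], profs[b]) <= theta:
                parent[find(a)] = find(b)
    groups = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


def test_two_viruses_group_correctly_and_match_oracle():
    v1 = make_virus("V1", divergence=0.0)
    v2 = make_virus(
        "V2",
        segment_lengths=[1650, 450],
        motif5="GGATCCGGATCCGGATCCGGATCCGGATCC",
        motif3="CAGTTACAGTTACAGTTACAGTTACAGTTA",
        divergence=0.0,
    )
    genomes = build_genomes(make_spec([v1, v2]), 7)
    segments = {
        f"{name}_s{i}": seq for name, segs in genomes for i, seq in enumerate(segs)
    }
    sets = group_full_length(segments)
    partition = sorted(sorted(g.segment_ids) for g in sets)
    assert partition == [["V1_s0", "V1_s1"], ["V2_s0", "V2_s1"]]
    assert partition == _exhaustive_partition_oracle(segments, 30, 0.2)


def test_shared_rdrp_termini_merge_into_one_ambiguous_set():
    """Viruses whose RdRp segments share termini cannot be split apart."""
    motif5 = "ACGTACGTACGTACGTACGTACGTACGTAC"
    motif3 = "TTGGCCAATTGGCCAATTGGCCAATTGGCC"
    viruses = [
        make_virus(f"S{i}", segment_lengths=[1700], motif5=motif5, motif3=motif3)
        for i in range(4)
    ]
    genomes = build_genomes(make_spec(viruses), 9)
    segments = {name: segs[0] for name, segs in genomes}
    sets = group_full_length(segments, rdrp_segment_ids=set(segments))
    assert len(sets) == 1
    (gs,) = sets
    assert len(gs.rdrp_segment_ids) == 4
    assert gs.ambiguous


def test_grouping_recovery_across_seeds():
    """Default-community genome sets are recovered from planted truth."""
    n_ok = 0
    trials = 30
    for seed in range(trials):
        spec = lichen_community_spec(seed=seed)
        genomes = build_genomes(spec, seed)
        segments, truth = {}, {}
        for name, segs in genomes[:7]:
            for i, seq in enumerate(segs):
                sid = f"{name}_s{i}"
                segments[sid] = seq
                truth[sid] = name
        sets = group_full_length(segments)
        recovered = sorted(sorted(g.segment_ids) for g in sets)
        planted = {}
        for sid, name in truth.items():
            planted.setdefault(name, []).append(sid)
        expected = sorted(sorted(g) for g in planted.values())
        if recovered == expected:
            n_ok += 1
    assert n_ok >= round(0.95 * trials)


def test_pfm_unit_columns_for_singleton():
    pfm5, pfm3 = build_pfm({"s": "ACGT" * 100}, w=20)
    assert pfm5.shape == (4, 20)
    assert np.allclose(pfm5.sum(axis=0), 1.0)
    assert np.allclose(pfm5.max(axis=0), 1.0)  # unit vectors
    pfm5b, _ = build_pfm({"a": "ACGT" * 100, "b": "ACGT" * 100}, w=20)
    assert np.allclose(pfm5, pfm5b)


def test_pfm_majority_frequency_under_divergence():
    """Per-column majority frequency tracks 1 - divergence."""
    p, n_members, w = 0.05, 200, 30
    rng = np.random.default_rng(3)
    motif = "".join(rng.choice(list("ACGT"), size=w))
    members = {}
    for i in range(n_members):
        seq = list(motif + "G" * 200 + motif)
        for j in list(range(w)) + list(range(len(seq) - w, len(seq))):
            if rng.random() < p:
                seq[j] = "ACGT".replace(seq[j], "")[rng.integers(3)]
        members[f"m{i}"] = "".join(seq)
    pfm5, pfm3 = build_pfm(members, w)
    sd = np.sqrt(p * (1 - p) / n_members)
    for pfm in (pfm5, pfm3):
        assert np.allclose(pfm.sum(axis=0), 1.0)
        majority = pfm.max(axis=0)
        assert np.all(majority >= (1 - p) - 3 * sd - 0.02)
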