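"""Synthetic lichen-community generator: genomes, libraries, ground truth.

The generator plants exactly the structure the downstream analysis relies
on, so every pipeline stage is verifiable by parameter recovery:

* segmented virus genomes (1-4 segments) whose segments share the same
  5'/3' terminal motif within a virus, diverged per segment at a small
  per-base rate — the signal used for genome-set grouping;
* one designated segment per virus carrying an open reading frame derived
  from a bundled labelled RdRp protein panel — the signal used for
  translated-search detection and family labelling;
* a dsRNA-seq library dominated by a few high-coverage ("major") viruses
  with a small residual rRNA fraction, and an ssRNA-seq library dominated
  by host rRNA with trace viral reads;
* a configurable fraction of viral fragments anchored exactly at segment
  ends, emulating the terminus enrichment of full-length cDNA chemistry —
  the signal used for terminus calling.

Every read pair is paired with one ground-truth record (class, source,
fragment coordinates, strand), and all randomness flows from one root
seed through per-purpose child streams, so identical spec + seed gives
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from segvirome import panels
from segvirome.seqio import ReadPair, revcomp, write_fasta, write_fastq_pair

CLASS_ORDER = ("rRNA", "major_virus", "minor_virus", "other")

_NT = np.array(list("ACGT"))
_AA = "ACDEFGHIKLMNPQRSTVWY"

# standard genetic code, inverted: amino acid -> codons
_CODONS: dict[str, list[str]] = {}
_STOPS = ["TAA", "TAG", "TGA"]
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
for _codon, _aa in _CODE.items():
    _CODONS.setdefault(_aa, []).append(_codon)


def child_rng(seed: int, purpose: str) -> np.random.Generator:
    """Independent RNG stream for one purpose under one root seed."""
    key = sum(ord(c) * 131**i for i, c in enumerate(purpose)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT, size=length))


@dataclass
class TaxonSpec:
    """A background (cellular) taxon contributing rRNA reads.

    If ``reference_id`` names an entry of the bundled SSU panel, that
    sequence is used verbatim (so rRNA filtering and SSU profiling can
    recognise the reads); otherwise a random sequence of ``rrna_length``
    is drawn.
    """

    name: str
    class_label: str
    relative_abundance: float
    rrna_length: int = 1200
    reference_id: str | None = None


@dataclass
class VirusSpec:
    """One segmented RNA virus with conserved terminal motifs."""

    name: str
    n_segments: int
    segment_lengths: list[int]
    terminal_motif_5p: str
    terminal_motif_3p: str
    within_motif_divergence: float
    has_rdrp_on_segment: int
    relative_abundance: float
    is_major: bool
    rdrp_panel_id: str = "RdRp_Partitiviridae_1"
    rdrp_aa_divergence: float = 0.1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (1 <= self.n_segments <= 4):
            raise ValueError(f"{self.name}: n_segments must be in [1, 4]")
        if len(self.segment_lengths) != self.n_segments:
            raise ValueError(f"{self.name}: segment_lengths length != n_segments")
        if any(l < 300 for l in self.segment_lengths):
            raise ValueError(f"{self.name}: every segment must be >= 300 nt")
        if not (0 <= self.has_rdrp_on_segment < self.n_segments):
            raise ValueError(f"{self.name}: has_rdrp_on_segment out of range")
        if self.segment_lengths[self.has_rdrp_on_segment] < 1600:
            raise ValueError(
                f"{self.name}: RdRp segment must be >= 1600 nt so the >1.5 kb "
                "OTU length rule is exercisable"
            )
        if not self.terminal_motif_5p or not self.terminal_motif_3p:
            raise ValueError(f"{self.name}: terminal motifs must be non-empty")


@dataclass
class CommunitySpec:
    """Full description of a synthetic community and its two libraries."""

    viruses: list[VirusSpec]
    background_taxa: list[TaxonSpec]
    dsrna_class_fractions: dict[str, float]
    ssrna_class_fractions: dict[str, float]
    read_length: int = 250
    fragment_length_mean: int = 450
    fragment_length_sd: int = 50
    substitution_error_rate: float = 0.002
    n_read_pairs_dsrna: int = 50_000
    n_read_pairs_ssrna: int = 20_000
    seed: int = 0
    terminal_anchor_frac: float = 0.1
    n_other_sequences: int = 5
    other_sequence_length: int = 3000

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, fracs in (
            ("dsrna_class_fractions", self.dsrna_class_fractions),
            ("ssrna_class_fractions", self.ssrna_class_fractions),
        ):
            if set(fracs) != set(CLASS_ORDER):
                raise ValueError(f"{name} must have keys {CLASS_ORDER}")
            if any(v < 0 for v in fracs.values()):
                raise ValueError(f"{name}: fractions must be >= 0")
            if abs(sum(fracs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}: fractions must sum to 1")
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        if self.n_read_pairs_dsrna < 0 or self.n_read_pairs_ssrna < 0:
            raise ValueError("read pair counts must be >= 0")
        if not (0 <= self.terminal_anchor_frac <= 1):
            raise ValueError("terminal_anchor_frac must be in [0, 1]")
        for virus in self.viruses:
            virus.validate()

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CommunitySpec":
        payload = yaml.safe_load(Path(path).read_text())
        payload["viruses"] = [VirusSpec(**v) for v in payload["viruses"]]
        payload["background_taxa"] = [TaxonSpec(**t) for t in payload["background_taxa"]]
        return cls(**payload)


def _mutate_protein(prot: str, rate: float, rng: np.random.Generator) -> str:
    out = list(prot)
    for i in range(1, len(out)):  # keep the initial Met
        if rng.random() < rate:
            choices = _AA.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def back_translate(prot: str, rng: np.random.Generator) -> str:
    """Random-synonymous-codon nucleotide ORF for *prot*, stop included."""
    codons = [
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in prot
    ]
    codons.append(_STOPS[rng.integers(3)])
    return "".join(codons)


def _diverge(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i, base in enumerate(out):
        if rng.random() < rate:
            choices = "ACGT".replace(base, "")
            out[i] = choices[rng.integers(3)]
    return "".join(out)


def build_genomes(
    spec: CommunitySpec, seed: int | None = None
) -> list[tuple[str, list[str]]]:
    """Construct all virus genomes of *spec*.

    Each segment is ``5' motif + filler + ORF + filler + 3' motif`` with
    the virus's motifs diverged per segment at ``within_motif_divergence``.
    The designated RdRp segment's ORF encodes a mutated copy of the
    virus's panel protein; other segments carry a long random ORF (a
    stand-in coat/unknown protein) so that coding-strand orientation is
    recoverable downstream.  Deterministic given spec + seed.
    """
    spec.validate()
    rng = child_rng(spec.seed if seed is None else seed, "genomes")
    prot_panel, _ = panels.load_rdrp_panel()
    genomes: list[tuple[str, list[str]]] = []
    for virus in spec.viruses:
        if virus.rdrp_panel_id not in prot_panel:
            raise ValueError(f"{virus.name}: unknown panel id {virus.rdrp_panel_id}")
        segments = []
        for si, seg_len in enumerate(virus.segment_lengths):
            m5 = _diverge(virus.terminal_motif_5p, virus.within_motif_divergence, rng)
            m3 = _diverge(virus.terminal_motif_3p, virus.within_motif_divergence, rng)
            interior = seg_len - len(m5) - len(m3)
            if si == virus.has_rdrp_on_segment:
                prot = _mutate_protein(
                    prot_panel[virus.rdrp_panel_id], virus.rdrp_aa_divergence, rng
                )
                orf = back_translate(prot, rng)
            else:
                n_aa = (interior - 6) // 3 - 1
                if n_aa < 20:
                    raise ValueError(
                        f"{virus.name} segment {si}: too short for motifs plus a "
                        f"minimal ORF ({seg_len} nt)"
                    )
                prot = "M" + "".join(
                    _AA[rng.integers(20)] for _ in range(n_aa - 1)
                )
                orf = back_translate(prot, rng)
            pad = interior - len(orf)
            if pad < 0:
                raise ValueError(
                    f"{virus.name} segment {si}: {seg_len} nt is shorter than "
                    f"motifs plus the {len(orf)} nt ORF"
                )
            left = pad // 2
            segment = m5 + random_dna(rng, left) + orf + random_dna(rng, pad - left) + m3
            assert len(segment) == seg_len
            segments.append(segment)
        genomes.append((virus.name, segments))
    return genomes


@dataclass
class _Source:
    """One sequence fragments can be drawn from."""

    name: str
    seq: str
    anchored: bool  # viral segments get terminus-anchored fragments


def _class_sources(
    spec: CommunitySpec,
    genomes: list[tuple[str, list[str]]],
    rng_other: np.random.Generator,
) -> dict[str, tuple[list[_Source], np.ndarray]]:
    """Per class: fragment sources and the probability of each source."""
    ssu_seqs, _ = panels.load_ssu_panel()
    by_name = dict(genomes)
    out: dict[str, tuple[list[_Source], np.ndarray]] = {}

    rrna_sources, rrna_w = [], []
    for taxon in spec.background_taxa:
        if taxon.reference_id is not None:
            if taxon.reference_id not in ssu_seqs:
                raise ValueError(f"unknown SSU reference {taxon.reference_id}")
            seq = ssu_seqs[taxon.reference_id]
        else:
            seq = random_dna(rng_other, taxon.rrna_length)
        rrna_sources.append(_Source(taxon.name, seq, False))
        rrna_w.append(taxon.relative_abundance)
    out["rRNA"] = (rrna_sources, np.asarray(rrna_w, dtype=float))

    for cls, major in (("major_virus", True), ("minor_virus", False)):
        sources, weights = [], []
        for virus in spec.viruses:
            if virus.is_major != major:
                continue
            segs = by_name[virus.name]
            total = sum(len(s) for s in segs)
            for si, seq in enumerate(segs):
                sources.append(_Source(f"{virus.name}/seg{si + 1}", seq, True))
                weights.append(virus.relative_abundance * len(seq) / total)
        out[cls] = (sources, np.asarray(weights, dtype=float))

    other_sources = [
        _Source(f"other_{i + 1}", random_dna(rng_other, spec.other_sequence_length), False)
        for i in range(spec.n_other_sequences)
    ]
    out["other"] = (other_sources, np.ones(len(other_sources)))
    return out


def simulate_library(
    genomes: list[tuple[str, list[str]]],
    spec: CommunitySpec,
    library: Literal["dsRNA", "ssRNA"],
    seed: int | None = None,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate one paired-end library plus its ground-truth table.

    Class counts are multinomial with the library's fractions.  Within a
    viral segment a deterministic ``ceil(terminal_anchor_frac * n)`` of
    fragments are anchored exactly at a segment end (split between the
    ends); all other fragments start uniformly.  Substitution errors are
    i.i.d. per base.  Truth coordinates are 0-based half-open on the plus
    strand of the written source sequence.
    """
    if library not in ("dsRNA", "ssRNA"):
        raise ValueError("library must be 'dsRNA' or 'ssRNA'")
    root = spec.seed if seed is None else seed
    fracs = (
        spec.dsrna_class_fractions if library == "dsRNA" else spec.ssrna_class_fractions
    )
    n_pairs = spec.n_read_pairs_dsrna if library == "dsRNA" else spec.n_read_pairs_ssrna

    rng_counts = child_rng(root, f"{library}:counts")
    rng_frag = child_rng(root, f"{library}:fragments")
    rng_err = child_rng(root, f"{library}:errors")
    rng_other = child_rng(root, f"{library}:other_sources")

    sources = _class_sources(spec, genomes, rng_other)
    class_counts = rng_counts.multinomial(n_pairs, [fracs[c] for c in CLASS_ORDER])

    # (class, source, start, end, strand) per fragment
    frags: list[tuple[str, str, int, int, str]] = []
    read_len = spec.read_length
    for cls, count in zip(CLASS_ORDER, class_counts):
        if count == 0:
            continue
        pool, weights = sources[cls]
        if not pool:
            raise ValueError(
                f"{library}: class '{cls}' has fraction > 0 but no source sequences"
            )
        p = weights / weights.sum()
        picks = rng_frag.choice(len(pool), size=count, p=p)
        for src_idx in range(len(pool)):
            n_src = int((picks == src_idx).sum())
            if n_src == 0:
                continue
            src = pool[src_idx]
            L = len(src.seq)
            lens = np.clip(
                np.rint(
                    rng_frag.normal(spec.fragment_length_mean, spec.fragment_length_sd, n_src)
                ).astype(int),
                min(read_len, L),
                L,
            )
            n_anchor = (
                math.ceil(spec.terminal_anchor_frac * n_src) if src.anchored else 0
            )
            n5 = math.ceil(n_anchor / 2)
            starts = np.empty(n_src, dtype=int)
            starts[:n5] = 0
            starts[n5:n_anchor] = L - lens[n5:n_anchor]
            u = rng_frag.random(n_src - n_anchor)
            starts[n_anchor:] = np.floor(u * (L - lens[n_anchor:] + 1)).astype(int)
            strands = np.where(rng_frag.random(n_src) < 0.5, "+", "-")
            for j in range(n_src):
                s = int(starts[j])
                frags.append((cls, src.name, s, s + int(lens[j]), str(strands[j])))
            # keep src.seq accessible later by name
        sources[cls] = (pool, weights)

    # blind the read order with respect to class
    order = child_rng(root, f"{library}:shuffle").permutation(len(frags))
    frags = [frags[i] for i in order]

    seq_by_name = {
        src.name: src.seq for pool, _ in sources.values() for src in pool
    }
    pairs: list[ReadPair] = []
    records = []
    err = spec.substitution_error_rate
    prefix = "ds" if library == "dsRNA" else "ss"
    for i, (cls, src_name, start, end, strand) in enumerate(frags):
        frag = seq_by_name[src_name][start:end]
        if strand == "-":
            frag = revcomp(frag)
        r1 = frag[:read_len]
        r2 = revcomp(frag)[:read_len]
        if err > 0:
            r1 = _apply_errors(r1, err, rng_err)
            r2 = _apply_errors(r2, err, rng_err)
        read_id = f"{prefix}_{i:07d}"
        pairs.append(ReadPair(read_id, r1, r2))
        records.append((read_id, library, cls, src_name, start, end, strand))

    truth = pd.DataFrame(
        records,
        columns=["read_id", "library", "class", "source", "start0", "end0_halfopen", "strand"],
    )
    return pairs, truth


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    codes = {65: "CGT", 67: "AGT", 71: "ACT", 84: "ACG"}
    for i in hits:
        alt = codes.get(int(arr[i]))
        if alt is not None:
            arr[i] = ord(alt[rng.integers(3)])
    return arr.tobytes().decode("ascii")


def simulate_to_files(
    spec: CommunitySpec,
    out_dir: str | Path,
    libraries: tuple[str, ...] = ("dsRNA", "ssRNA"),
    seed: int | None = None,
) -> dict[str, dict[str, Path]]:
    """Generate genomes + libraries and write FASTQ/FASTA/TSV artefacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = spec.seed if seed is None else seed
    genomes = build_genomes(spec, root)
    write_fasta(
        out_dir / "genomes.fasta",
        [
            (f"{name}/seg{i + 1}", seq)
            for name, segs in genomes
            for i, seq in enumerate(segs)
        ],
    )
    spec.to_yaml(out_dir / "community.yaml")
    out: dict[str, dict[str, Path]] = {}
    for library in libraries:
        pairs, truth = simulate_library(genomes, spec, library, root)
        prefix = out_dir / library.lower()
        p1, p2 = write_fastq_pair(prefix, pairs)
        truth_path = out_dir / f"{library.lower()}_truth.tsv"
        truth.to_csv(truth_path, sep="\t", index=False)
        out[library] = {"r1": p1, "r2": p2, "truth": truth_path}
    return out


def rdrp_lineage_set(
    n_lineages: int = 65,
    n_partiti: int = 17,
    variants_per_lineage: int = 2,
    length: int = 2000,
    variant_divergence: float = 0.05,
    aa_divergence: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Construct an RdRp nucleotide sequence set with known OTU structure.

    ``n_lineages`` mutually distinct lineages are built by independently
    back-translating mutated panel proteins (independent synonymous codon
    choices keep inter-lineage nucleotide identity far below any
    clustering threshold); the first ``n_partiti`` derive from
    Partitiviridae panel proteins and the rest cycle through the other
    families.  Each lineage gets ``variants_per_lineage`` redundant
    variants at ~``1 - variant_divergence`` nucleotide identity.

    Returns (sequences by id, true lineage by id, true family by lineage).
    """
    rng = child_rng(seed, "rdrp_lineages")
    prot_panel, families = panels.load_rdrp_panel()
    partiti = sorted(pid for pid, fam in families.items() if fam == "Partitiviridae")
    others = sorted(pid for pid, fam in families.items() if fam != "Partitiviridae")
    sequences: dict[str, str] = {}
    lineage_of: dict[str, str] = {}
    family_of: dict[str, str] = {}
    for i in range(n_lineages):
        pid = partiti[i % len(partiti)] if i < n_partiti else others[(i - n_partiti) % len(others)]
        prot = _mutate_protein(prot_panel[pid], aa_divergence, rng)
        orf = back_translate(prot, rng)
        pad = max(0, length - len(orf))
        left = pad // 2
        seq = random_dna(rng, left) + orf + random_dna(rng, pad - left)
        lid = f"lineage_{i + 1:03d}"
        sequences[lid] = seq
        lineage_of[lid] = lid
        family_of[lid] = families[pid]
        for v in range(variants_per_lineage):
            vid = f"{lid}_v{v + 1}"
            sequences[vid] = _diverge(seq, variant_divergence, rng)
            lineage_of[vid] = lid
    return sequences, lineage_of, family_of


def _random_motif(rng: np.random.Generator, w: int) -> str:
    return random_dna(rng, w)


def lichen_community_spec(
    n_read_pairs_dsrna: int = 50_000,
    n_read_pairs_ssrna: int = 20_000,
    seed: int = 0,
    w_motif: int = 30,
    dominant_share_dsrna: float = 0.94,
    dominant_share_ssrna: float = 0.87,
    n_minor: int = 5,
    shared_rdrp_termini: bool = False,
) -> CommunitySpec:
    """Default study-conditions community.

    Seven major multi-segment viruses (segment counts 2,2,4,2,2,2,2;
    six partiti-like plus one unplaced lineage) at abundances proportional
    to genome length, so that at the default dsRNA depth every major
    segment exceeds 1000x coverage; ``n_minor`` single-segment RdRp-bearing
    minor viruses; a cellular background whose SSU classes follow the
    fungal-dominated lichen profile (Lecanoromycetes 0.43, two
    Trebouxiophyceae phylotypes totalling 0.17, remaining fungi and moss
    classes making up the rest).

    Library class fractions follow the read-accounting table of a
    dsRNA/ssRNA lichen survey: dsRNA 4.0 % rRNA / 84.4 % major virus /
    11.6 % other; ssRNA 93.8 % rRNA / 0.2 % major virus / 6.0 % other.
    The minor-virus slice of "other" is solved analytically so that the
    dominant segments hold ``dominant_share_*`` of total RdRp-region
    coverage in each library.

    With ``shared_rdrp_termini`` the four 2-segment partiti-like majors
    after the first two share one terminal motif pair, reproducing the
    situation where genome sets cannot be distinguished because their
    RdRp segments share termini.
    """
    rng = child_rng(seed, "community_motifs")
    major_cfg = [
        ("LpaRV1", [1750, 500], "RdRp_Partitiviridae_1"),
        ("LpaRV2", [1700, 450], "RdRp_Partitiviridae_2"),
        ("LpaRV3", [1700, 500, 450, 400], "RdRp_Partitiviridae_3"),
        ("LpaRV4", [1650, 500], "RdRp_Partitiviridae_4"),
        ("LpaRV5", [1700, 550], "RdRp_Partitiviridae_1"),
        ("LpaRV6", [1750, 450], "RdRp_Partitiviridae_2"),
        ("LRV1", [1700, 500], "RdRp_unclassified_1"),
    ]
    shared = (_random_motif(rng, w_motif), _random_motif(rng, w_motif))
    viruses: list[VirusSpec] = []
    g_total = 0
    for name, seg_lens, panel_id in major_cfg:
        if shared_rdrp_termini and name in ("LpaRV3", "LpaRV4", "LpaRV5", "LpaRV6"):
            m5, m3 = shared
        else:
            m5, m3 = _random_motif(rng, w_motif), _random_motif(rng, w_motif)
        g_total += sum(seg_lens)
        viruses.append(
            VirusSpec(
                name=name,
                n_segments=len(seg_lens),
                segment_lengths=seg_lens,
                terminal_motif_5p=m5,
                terminal_motif_3p=m3,
                within_motif_divergence=0.02,
                has_rdrp_on_segment=0,
                relative_abundance=float(sum(seg_lens)),
                is_major=True,
                rdrp_panel_id=panel_id,
                rdrp_aa_divergence=0.1,
            )
        )
    minor_panels = [
        "RdRp_Totiviridae_1",
        "RdRp_Narnaviridae_1",
        "RdRp_Chrysoviridae_1",
        "RdRp_Endornaviridae_1",
        "RdRp_Hypoviridae_1",
    ]
    minor_len = 1700
    for i in range(n_minor):
        viruses.append(
            VirusSpec(
                name=f"MV{i + 1}",
                n_segments=1,
                segment_lengths=[minor_len],
                terminal_motif_5p=_random_motif(rng, w_motif),
                terminal_motif_3p=_random_motif(rng, w_motif),
                within_motif_divergence=0.02,
                has_rdrp_on_segment=0,
                relative_abundance=1.0,
                is_major=False,
                rdrp_panel_id=minor_panels[i % len(minor_panels)],
                rdrp_aa_divergence=0.1,
            )
        )

    background = [
        TaxonSpec("Lecanoromycetes_sp", "Lecanoromycetes", 0.43, reference_id="SSU_Lecanoromycetes_1"),
        TaxonSpec("Trebouxiophyceae_ph1", "Trebouxiophyceae", 0.10, reference_id="SSU_Trebouxiophyceae_1"),
        TaxonSpec("Trebouxiophyceae_ph2", "Trebouxiophyceae", 0.07, reference_id="SSU_Trebouxiophyceae_2"),
        TaxonSpec("Sordariomycetes_sp", "Sordariomycetes", 0.12, reference_id="SSU_Sordariomycetes_1"),
        TaxonSpec("Dothideomycetes_sp", "Dothideomycetes", 0.08, reference_id="SSU_Dothideomycetes_1"),
        TaxonSpec("Eurotiomycetes_sp", "Eurotiomycetes", 0.06, reference_id="SSU_Eurotiomycetes_1"),
        TaxonSpec("Agaricomycetes_sp", "Agaricomycetes", 0.05, reference_id="SSU_Agaricomycetes_1"),
        TaxonSpec("Tremellomycetes_sp", "Tremellomycetes", 0.04, reference_id="SSU_Tremellomycetes_1"),
        TaxonSpec("Bryopsida_sp", "Bryopsida", 0.05, reference_id="SSU_Bryopsida_1"),
    ]

    n_major = len(major_cfg)

    def minor_fraction(major_frac: float, share: float) -> float:
        # minor RdRp-coverage slice solving
        #   share = sum(major cov) / (sum(major cov) + sum(minor cov))
        # with major abundances proportional to genome length
        return n_major * major_frac / g_total * (1 - share) / share * minor_len

    m_ds = minor_fraction(0.844, dominant_share_dsrna)
    m_ss = minor_fraction(0.002, dominant_share_ssrna)
    ds_fracs = {
        "rRNA": 0.040,
        "major_virus": 0.844,
        "minor_virus": m_ds,
        "other": 0.116 - m_ds,
    }
    ss_fracs = {
        "rRNA": 0.938,
        "major_virus": 0.002,
        "minor_virus": m_ss,
        "other": 0.060 - m_ss,
    }
    return CommunitySpec(
        viruses=viruses,
        background_taxa=background,
        dsrna_class_fractions=ds_fracs,
        ssrna_class_fractions=ss_fracs,
        n_read_pairs_dsrna=n_read_pairs_dsrna,
        n_read_pairs_ssrna=n_read_pairs_ssrna,
        seed=seed,
    )
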