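# segvirome

Reconstruction of segmented RNA virus genomes and community composition
from dsRNA-seq / ssRNA-seq read sets — with a synthetic community
generator that makes the whole analysis verifiable by parameter recovery.

## The problem

Double-stranded RNA marks active RNA virus infection: it is the genome of
dsRNA viruses and the replicative intermediate of ssRNA viruses.
Full-length-cDNA dsRNA sequencing chemistry preserves the true 5′/3′
termini of viral genome segments in the read set, which enables an
analysis ordinary RNA-seq cannot support:

1. **Terminus calling** — a contig end is a genuine segment terminus when
   many reads start/end exactly there (and nothing extends beyond it);
   contigs with two called termini are *full-length segments*.
2. **Genome sets** — segments of one multi-segment virus share conserved
   terminal sequences, so full-length segments are grouped into putative
   virus genomes by single-linkage clustering on terminal-window edit
   distance (w = 30 nt windows, mean of the normalised 5′ and 3′
   distances, join threshold θ = 0.2). Sets whose RdRp segments share
   termini are flagged ambiguous rather than force-split.
3. **RdRp OTUs** — RNA-dependent RNA polymerase, the universal hallmark
   gene, is detected by a six-frame translated search (local alignment,
   BLOSUM62, affine gaps, e-value ≤ 1e-5 against a bundled labelled
   panel); RdRp nucleotide regions > 1.5 kb are clustered at 90 %
   global identity (centroid-greedy, terminal gaps excluded).
4. **Dominance and accounting** — full-length segments with mean coverage
   > 1000× define the dominant viruses; every trimmed read pair is
   assigned to rRNA / major virus / other, giving a per-library
   composition table, and ssRNA rRNA reads are profiled against a
   labelled SSU panel at ≥ 98 % identity.

Upstream of all that sit an rRNA filter (canonical k-mer containment,
k = 15, τ = 0.2), a minimal greedy overlap assembler, and an ungapped
seed-and-verify read mapper; pre-assembled contigs (FASTA) and external
alignments (SAM) can be substituted at every boundary.

## Worked example

```python
from segvirome.community import lichen_community_spec
from segvirome.pipeline import run_pipeline, dominant_coverage_share, otu_richness

spec = lichen_community_spec(seed=1)   # 50k dsRNA + 20k ssRNA pairs
result = run_pipeline(spec, seed=1)

ds = result.composition["dsRNA"]
print(len(result.dominant_contigs))              # 16
print(len(result.genome_sets))                   # 12 (7 major + 5 minor viruses)
print(round(ds.pct_major_virus, 1), round(ds.pct_rrna, 1))   # 84.3 4.0
print(round(100 * dominant_coverage_share(result, "dsRNA"), 1))  # 94.1
print(otu_richness(result)["Partitiviridae"])    # 6
print({k: round(v, 2) for k, v in result.ssu_profile.abundances.items()})
# {'Agaricomycetes': 0.05, 'Bryopsida': 0.05, 'Dothideomycetes': 0.08,
#  'Eurotiomycetes': 0.06, 'Lecanoromycetes': 0.43, 'Sordariomycetes': 0.12,
#  'Trebouxiophyceae': 0.17, 'Tremellomycetes': 0.04}
```

The default community plants seven major multi-segment viruses (all
segments above 1000× at this depth), five minor RdRp-bearing viruses and
a fungus/alga-dominated cellular background; the pipeline reconstructs
all 16 major segments full-length, groups them into the seven planted
genome sets, and recovers the planted composition: 84.3 % of dsRNA pairs
map to dominant genome sets, 4.0 % are rRNA, the dominant segments hold
94.1 % of RdRp-OTU coverage, and the SSU profile returns the planted
43 % Lecanoromycetes / 17 % Trebouxiophyceae split.

The same stages are available from a shell:

```bash
segvirome simulate --out-dir sim --seed 1
segvirome filter-rrna --reads-1 sim/dsrna_R1.fastq --reads-2 sim/dsrna_R2.fastq --out-prefix filt
segvirome run --out-dir out --seed 1
```

## Layout

- `src/segvirome/community.py` — community spec, genome builder, read simulator
- `src/segvirome/rrna.py`, `kmers.py` — k-mer containment rRNA filter
- `src/segvirome/assembly.py`, `mapping.py` — greedy assembler, ungapped mapper, SAM import
- `src/segvirome/segments.py` — terminus calling, full-length classification, coverage
- `src/segvirome/otus.py` — translated RdRp search, OTU clustering, BLAST import
- `src/segvirome/genome_sets.py` — orientation, terminal distances, genome sets, PFMs
- `src/segvirome/reports.py`, `pipeline.py`, `cli.py` — reports and orchestration
- `src/segvirome/data/` — bundled synthetic reference panels (see `docs/methods.md`)
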