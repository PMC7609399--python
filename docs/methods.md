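# Methods

## Overview

`segvirome` reconstructs segmented RNA virus genomes from paired-end
dsRNA-seq reads and profiles the surrounding microbial community from a
companion ssRNA-seq library. The pipeline is: rRNA filtering → assembly
→ read mapping → terminus calling → RdRp detection and OTU clustering →
genome-set grouping by terminal conservation → composition reports.
Because the analysis targets properties that only synthetic data can
certify end to end (true termini, true genome-set partitions, true read
classes), the package ships a generator that plants every one of those
signals and emits machine-readable ground truth.

## The synthetic community generator

The generator emulates the statistical structure the analysis assumes,
not the biology that produces it.

**Genomes.** Each virus has 1–4 segments. A segment is
`5′ motif + filler + ORF + filler + 3′ motif`; the two motifs (default
w = 30 nt) are shared by all segments of a virus and diverged per
segment by an i.i.d. per-base substitution rate (default 0.02). The
designated RdRp segment's ORF encodes a mutated copy (default 10 %
amino-acid divergence) of a protein from the bundled panel,
back-translated with independently drawn synonymous codons; other
segments carry a long random ORF (a stand-in coat/unknown protein) that
covers most of the interior, so the coding strand is recoverable from
reading-frame structure alone.

**Libraries.** Read-pair class counts (rRNA / major virus / minor virus
/ other) are multinomial with per-library fractions. Fragments are
~N(450, 50) nt, clipped to [read length, source length]; reads are
250 nt, both strands, substitution errors i.i.d. at 0.002/base, constant
quality `I`. Within each viral segment a deterministic
`ceil(terminal_anchor_frac · n)` of fragments (default 10 %) start
exactly at a segment end, split between the two ends — this emulates the
terminus enrichment of template-switching full-length cDNA synthesis,
whose true rate is not known; it is exposed as a parameter and set so
termini are detectable from ~100× coverage. Read ids are positional
only; order is shuffled so ids encode nothing about class. One root
seed feeds per-purpose child streams (genomes, counts, fragments,
errors, shuffle), so identical spec + seed reproduces byte-identical
FASTQ and truth tables, and changing the read count does not perturb
the genomes.

**Default community (the study conditions).** Seven major viruses with
segment counts 2,2,4,2,2,2,2 — six partiti-like lineages and one
unplaced lineage — and five single-segment minor RdRp viruses. Major
abundances are proportional to genome length so that at 50,000 dsRNA
pairs every major segment sits near 1300×, comfortably above the 1000×
dominance rule; minors land near 115×. Library fractions follow the
published accounting of a lichen dsRNA/ssRNA survey: dsRNA 4.0 % rRNA /
84.4 % major virus / 11.6 % other; ssRNA 93.8 % rRNA / 0.2 % major
virus / 6.0 % other. The minor-virus slice within "other" is solved in
closed form so the dominant segments hold a chosen share of total
RdRp-region coverage (94 % dsRNA, 87 % ssRNA by default). The cellular
background plants the published SSU profile: Lecanoromycetes 0.43, two
Trebouxiophyceae phylotypes totalling 0.17, and five further fungal and
moss classes. Scaled-down problem sizes (50k dsRNA / 20k ssRNA pairs)
keep a full run at a few minutes on one CPU; at the 20k ssRNA depth the
minor-virus viral slice is only ~4 expected pairs, so the recovered
ssRNA coverage share carries an analytic SD of ~5–6 percentage points —
tests bound it accordingly.

**What the generator does not model** (and hence what green tests do not
certify about real data): indels, quality decay, PCR duplicates,
chimeras, adapter read-through, strand bias, codon usage, real RdRp
motif conservation, rRNA secondary-structure conservation, and any
homology between the bundled panels and real sequences.

## Bundled panels

Both reference panels are *synthetic stand-ins*: random protein
sequences labelled with RNA-virus family names (four Partitiviridae
entries plus one entry for each of eleven further families and one
"unclassified"), and random 1200 nt sequences labelled with SSU classes.
They exist so detection, labelling and profiling logic can be verified
by parameter recovery; they make no claim to biological homology.
Protein lengths are 505–530 aa so the encoded ORF (1518–1593 nt) always
exceeds the 1.5 kb OTU length rule. `scripts/make_panels.py`
regenerates them deterministically.

## Stage-by-stage choices

**rRNA filter.** Canonical (strand-collapsed) k-mer containment:
a read is rRNA when shared-window fraction ≥ τ. Defaults k = 15,
τ = 0.2: an rRNA read with 2 % errors has expected containment
≈ 0.98¹⁵ ≈ 0.74, while an unrelated 250 nt read's expected containment
is |index|/4¹⁵ ~ 10⁻⁵ — the operating point separates them by orders of
magnitude. k must be odd (canonical form of an even palindromic k-mer
is ill-defined); windows containing N are skipped, not matched. A pair
is removed if either mate classifies rRNA (conservative removal, the
usual practice).

**Assembly.** A minimal greedy overlap assembler for substitution-only
desk-scale data. Contigs grow from seed reads (input order) by repeated
best suffix-prefix merges — longest extension, then fewest mismatches,
then lexicographic read id — requiring overlap ≥ 50 nt with mismatch
fraction ≤ 0.05, both orientations. Merge candidates are found through
an exact 21-mer index over several prefix offsets of each oriented read
(several probes, so a single substitution error in read or contig
cannot hide an overlap), and every candidate is verified over the full
overlap; sequences sharing only a ≤ 30 nt terminal motif can never
merge (no chimeras across segments of one virus). After a contig stops growing, all reads placeable end-to-end on
it are marked consumed; occasional unconsumed error-rich reads seed
short artefact contigs, which downstream length/coverage rules ignore.
The stage is pluggable: `--contigs` accepts external FASTA.

**Mapping.** Best ungapped end-to-end placement per read, either
strand, found by probing non-overlapping read k-mers (k = 15) against a
contig position index and verifying mismatch counts (≤ 5 %). Ties break
to the lowest (contig, position, strand); a read tying across
placements is flagged *ambiguous*. SAM import accepts only M/=/X
records (indel/clipped records are skipped with a logged count) so the
two routes stay comparable; SAM's 1-based coordinates convert at the
boundary — internally everything is 0-based half-open.

**Terminus calling.** Contigs are first trimmed to their covered span
(assemblers may append unsupported bases). A terminus passes iff
≥ min_support (5) non-ambiguous reads start (5′) or end (3′) exactly at
the extreme coordinate, those reads are ≥ min_fraction (0.1) of the
coverage at the adjacent base, and no alignment extends beyond.
Ambiguous reads are excluded from support — segments of one virus share
terminal windows, and tied reads would otherwise manufacture support —
but still count toward coverage. Defaults are set so 100× coverage
with 10 % anchoring passes with high probability. Full-length =
both termini pass; dominance = full-length and mean coverage
strictly > 1000×.

**RdRp detection.** Six-frame translation; each frame locally aligned
(BLOSUM62, gap open −11 / extend −1) against every panel protein,
prefiltered by a shared amino-acid 5-mer. E-values use the extreme-value
formula E = K·m·n·e^(−λS) with the standard gapped BLOSUM62 constants
K = 0.041, λ = 0.267 and database size = total panel residues; hits are
kept at E ≤ 10⁻⁵. The clustered nucleotide sequence is the union of the
best-hit region and the in-frame stop-free run containing it, on the
coding strand — the union is robust to the rare contig error that
introduces a spurious in-frame stop inside the gene.

**OTU clustering.** Centroid-greedy at 90 % global identity, length
strictly > 1500 nt. Identity = matches / alignment columns with
internal gaps counted and terminal gaps excluded (the documented default
semantics of the standard greedy clustering tools). Processing order is
length descending with lexicographic tie-break, so the partition is
independent of input order. Banded edit distance (reject below 50 %
identity) keeps the all-vs-centroid comparisons fast.

**Genome sets.** Segments are oriented to the coding strand (best RdRp
hit frame, else longest stop-free frame run; plus strand on ties).
Distance between two segments is the mean of the normalised edit
distances of their 5′ and 3′ w = 30 windows; single linkage joins at
θ = 0.2. Under the generator's divergence (≤ 0.05) the expected
within-virus distance is ≈ 0.07, while unrelated 30-mers sit near 0.69
(expected normalised edit distance of random DNA), so θ = 0.2 and the
ambiguity band θ_ambig = 0.35 separate the two regimes by a wide
margin. Near-misses in (θ, θ_ambig] are cross-listed as ambiguous;
sets with ≥ 2 RdRp-bearing segments are flagged ambiguous rather than
split — the published situation where several viruses' RdRp segments
share termini and their genome sets cannot be distinguished. Each set
carries 5′/3′ position-frequency matrices (pseudocount 0,
column-stochastic), the data behind terminal sequence logos.

**Composition and SSU profile.** Every trimmed pair gets exactly one
class with precedence rRNA → major virus → other; "major" means either
mate maps to any segment of a genome set containing a dominant segment,
and "other" is everything else including unmapped pairs (the three-way
table leaves no other place for them). SSU profiling assigns each
ssRNA rRNA read to its best end-to-end reference placement iff identity
≥ 0.98, then reports class abundances over assigned reads.

## Numerical and degenerate-input conventions

Percentages always use trimmed pairs as denominator and sum to 100 ±
0.1; abundance maps sum to 1 ± 10⁻⁶. Zero read pairs, empty classes
with zero fraction, unmapped reads, and zero-merge assemblies are all
valid outcomes, not errors; an empty reference panel, a class with
positive fraction but no sources, and mate-count mismatches are
validation errors. Coverage share over an all-zero coverage vector is
reported as not-applicable (`None`), never 0/0.

## Known limitations

The assembler and mapper are substitution-only by design (the simulator
emits no indels); real data should enter through the FASTA/SAM import
paths. The terminus criterion cannot see reads overhanging a truncated
contig (end-to-end mapping never places them), so it relies on the
absence of an exact start/end pileup — which the anchoring signal
guarantees only for true termini. Family labels are only as meaningful
as the bundled panel; with the synthetic panel they certify label
*plumbing*, not taxonomy. Genome-set grouping considers full-length
segments only; partial segments are never assigned to sets.
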