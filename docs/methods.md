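# Methods

## The model

Spliced-leader (SL) trans-splicing replaces a pre-mRNA's 5' region (the
outron, ending at an acceptor AG and usually carrying a pyrimidine-rich
tract) with the 5' exon of a small SL RNA. The SL RNA behaves like a
half-intron donor: its exon ends immediately before a GT splice donor, and
its intron-like remainder distinguishes gene subfamilies. Because
cap-trapper cDNA reads begin at the transcript's true 5' end, a
trans-spliced transcriptome shows one short word shared by the read starts
of many unrelated genes — with a fixed 3' boundary (the splice junction)
and ragged 5' starts when the SL gene is transcribed from several start
sites. Everything in this package reduces to detecting, locating, and
cross-validating that signature.

## Synthetic data: what it emulates and what it does not

The generator (`slseeker.simulate`) is the package's study system. Its
defaults are the conditions the analysis is designed for:

* a 33-nt leader exon ending in G whose 3'-terminal 20 nt are the published
  conserved core `TGGATAATCCGGCTTTTCTG`; the 5' 13 nt are synthetic — the
  complete natural leader is not publicly printed, so the default must not
  be read as the real sequence;
* 43 SL-I and 14 SL-II gene copies (the published family sizes) on both
  strands of single-locus contigs (mirroring a fragmented shotgun assembly),
  each `exon + GT + subtype intron` with per-site copy mutation (default
  1%, capped at 2 substitutions inside the conserved core — purifying
  selection on the functional segment, and the condition under which a
  2-mismatch scan is complete);
* SL-I intron template of 95 nt, so exon (33) + GT + intron = a 130-column
  conserved region; it carries two hairpin blocks and a pyrimidine-rich
  A…G tract (a relaxed Sm-site candidate) with C/A-rich linkers chosen so
  that an MFE fold leaves the tract single-stranded;
* SL-I transcription starts uniform on exon +1..+6 (six start positions are
  what the attached 28–33-nt leader lengths require); SL-II starts at +19;
* one third of loci carry `AATAAA` beginning exactly 70 nt after the
  conserved region's last base, with the last templated base 14 nt after
  the hexamer's end, and a 30-nt poly(A) tail on SL RNA transcripts; the
  base following the cleavage position is non-A, keeping the templated-A
  boundary of the poly(A) junction unambiguous;
* 20 recipient genes: outron of 80–200 nt containing a 10-nt C/T tract
  (with TTT) and ending in AG, a 20-nt 5' UTR, a 306-nt CDS interrupted by
  two GT..AG introns of 50–80 nt at least 30 nt apart, and an AATAAA/
  cleavage geometry matching the SL loci; trans-splicing probability 1.0
  per mature transcript with a 5% premature (unspliced) fraction;
* SL-I : SL-II transcript abundance 100 : 1;
* 2,000 cap-anchored reads, length ~ Normal(136, 30) truncated to
  [30, transcript length], 0.5% substitution errors, 10% bacterial
  contaminant and 5% rRNA reads drawn from synthetic references.

Spacer sequence is i.i.d. uniform ACGT screened by exact match against the
leader core (both strands); downstream-of-locus segments are additionally
screened against stray `AATAAA` and poly(T)-containing pyrimidine runs so
the planted motif census is exact. Indels, quality-score structure,
paired-end reads, and realistic expression dispersion are deliberately not
modeled; passing tests therefore demonstrate correctness of the method's
logic under its stated assumptions, not robustness to every artifact of
real libraries.

Ground truth tables use 1-based inclusive contig coordinates; positional
fields are stranded endpoints (they map onto the feature's own strand), and
gene-model coordinates are ATG-relative with no position 0, upstream
negative.

## Stage-by-stage choices

**Screening.** Contaminant screening is k-mer (k = 15) containment, where
containment is the fraction of read bases covered by a k-mer present in the
reference set (either strand). Base coverage rather than raw k-mer-set
fraction makes the decision robust to isolated sequencing errors: one error
removes at most one covered base instead of k k-mers. Threshold 0.8. An
external aligner's verdicts can replace this via the hit-table mode. The
translated screen seeds on exact 8-aa words from protein N-terminal 50-aa
windows and extends ungapped under BLOSUM62 (X-drop 20, threshold 40);
frames are split at stop codons.

**Clustering.** Reads are grouped by gene with greedy clustering on k-mer
sets of the read body past a 40-nt 5' window (k = 15, share ≥ 0.5 of the
read's k-mers with the cluster representative). Input is sorted by
descending length then id, making the greedy pass deterministic. Reads
shorter than 60 nt are set aside before clustering — they carry too few
body k-mers to place reliably. Grouping, not assembly, is all downstream
stages consume.

**Leader detection.** Words of 12 nt within the first 40 nt of cluster
representatives are counted across clusters; words present in ≥ 50% of
clusters are chained through (k−1)-overlaps (highest support first, ties
lexicographic) into a consensus. A consensus therefore recovers the leader
3' segment shared by at least half the clusters; with uniform starts at
+1..+6 this is positions ≥ +3 of the exon, and the 5'-most exon bases are
deliberately not claimed. Junctions allow ≤ 1 mismatch — enough for a
sequencing error, too little to absorb genomic 5'-UTR bases. The junction
position doubles as the attached-leader length because reads are
cap-anchored. Equal-support candidates rank by longer consensus, then
lexicographically.

**Genome scan.** The query is core + GT; the core may carry ≤ 2 mismatches
(pigeonhole-seeded scan), the donor is exact. Overlapping placements keep
the lowest mismatch count. Subtype clustering is single-linkage on
identity ≥ 0.8 of the 60 nt after the donor, identity computed as
1 − editdistance/max(length) (global alignment, so gaps count as
mismatches); clusters are named SL-I, SL-II, … by descending size, with
singletons and loci with < 20 nt of downstream sequence left `unassigned`
— which also covers real-data loci that fit no family.

**Conserved block.** Progressive alignment in pairwise-identity guide
order, profile consensus vs next sequence under match +1 / mismatch −1 /
gap −2, with once-a-gap-always-a-gap column propagation. Columns that are
mostly gaps (non-gap fraction < 0.5) are masked before scoring: an
insertion carried by a minority of rows — typically a flanking base
absorbed into a homopolymer run at the boundary — carries no family
signal and must not interrupt the block. Column conservation is the
modal-residue count divided by the total number of rows (gapped rows
count against the column; otherwise columns carried by one row score
1.0). The block extends from column 1 while 10-column windows average
≥ 0.9; trailing columns whose own conservation is below 0.7 are then
trimmed, so a window straddling the boundary cannot drag unconserved
columns in while a merely mutated column stays inside. The block end is
finally mapped from alignment columns to sequence coordinates as the
modal per-row position, making single-row homopolymer ambiguities
harmless. On the simulated SL-I family this yields exactly the planted
conserved region across seeds.

**3'-end geometry.** Offset conventions, fixed here and applied
consistently by generator and scanners: the poly(A)-signal offset is
(first base of AATAAA) − (last column of the conserved block), and the
cleavage offset is (last templated base) − (last base of AATAAA). Cleavage
is inferred from polyadenylated cDNAs by stripping the terminal A-run
(≥ 8), aligning the remainder, and restoring 3' A's that are genomic —
the standard 3'-RACE ambiguity rule. The signal census scans a bounded
110-nt window past the block (the extent a family alignment would
display), not the entire contig.

**TSS mapping.** Reads are accepted at identity ≥ 0.95 over > 0.9 of their
length (terminal poly(A) runs, transcript features absent from the genome,
are ignored for the alignment); the TSS is the genomic position of read
base 1. Modal positions are those with ≥ half the maximal count. The
leader length of a locus is the distance from the 5'-most mapped TSS to
the base before the donor; with family-pooled reads this recovers 33 nt.

**Folding.** The internal folder maximizes Watson-Crick + GU pairs
(Nussinov dynamic program, hairpin ≥ 3, traceback preferring unpaired i
then the smallest partner), verified against exhaustive enumeration for
short sequences. Pair maximization is a combinatorial approximation: it
over-pairs pyrimidine tracts that a thermodynamic fold leaves open, so the
single-strandedness requirement of the relaxed Sm-site scan should be
evaluated on an MFE structure when one is available (the `RNAfold` bridge
in `slseeker.fold.rnafold_structure`, or any externally supplied
dot-bracket). The reverse-complement pair-count invariance holds only for
pure Watson-Crick pairing and is tested with GU disabled. Stem-loops are
innermost hairpins extended outward across bulges of ≤ 3 nt per side;
stems under 3 bp are not reported.

**Validation.** The acceptor is found by stripping the mRNA's leader match
(longest leader suffix, ≥ 12 nt, ≤ 1 mismatch) and realigning the next
60 nt to the genome, falling back to 40/25/20-nt probes when the long probe
straddles the first cis intron; the preceding dinucleotide must be AG.
The trans verdict requires the leader (≤ 1 mismatch) to be absent from a
5-kb window upstream of the acceptor — a finite-window operationalization
of the "no long-range cis-splicing" argument — and, when capped reads are
supplied, no accepted start more than 50 nt upstream of the outron's start
cluster; missing read evidence degrades to `trans` with an explicit note.
Intron counting chains unique shared 20-mers by diagonal; a genomic gap of
≥ 40 nt between diagonals is an intron, its boundary slid within the
repeat-ambiguity window to match GT..AG when possible. Virtual PCR is
exact-match (products bounded by a forward match and a reverse-complement
match, forward 5' end upstream, ≤ 5 kb), reproducing the qualitative
presence/absence logic of the four-primer experiment.

## Problem sizes

The shipped scenarios are desk-scale: `tiny` (5 loci, 2 genes, 200
error-free reads) for fixtures, `default` (57 loci, 20 genes, 2,000 reads,
0.5% error, 1% copy mutation) for all headline measurements, and `stress`
(50 genes, 10,000 reads, 1% error, 2% mutation) for robustness checks. The
motif/PCR/fold oracle comparisons use 1,000 random 200-mers, 1,000 random
500-nt templates, and 300 random sequences of ≤ 20 nt respectively;
negative controls run ten no-trans-splicing simulations and ten per-read
shuffles. The real study's census numbers (hundreds of thousands of reads
against deposited accessions) are outside this package's scope and are not
claimed by any test.

## Known limitations

Greedy clustering is order-dependent by construction (made deterministic by
the length sort, not order-free); leader detection reports the consensus
segment shared by ≥ 50% of clusters rather than the full exon; subtype
naming by family size can differ from a naming based on expression;
base-pair-maximization structures are not energy-ranked; and the
cis/trans verdict is as strong as the genomic window and read evidence
provided to it.
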