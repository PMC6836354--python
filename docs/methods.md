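# Methods

This note documents the models and procedures behind each pipeline stage,
the defaults and why they were chosen, the design of the synthetic data,
and the limits of what the tests demonstrate.

## Coordinates, sequences, alphabets

All internal coordinates are 0-based half-open on the forward strand;
reports use 1-based inclusive (GenBank convention). Circular genomes wrap:
slices, ORF calls, presence searches and repeat discovery all operate on
the doubled sequence with results normalized modulo the genome length.
Sequences are restricted to {A, C, G, T, N}; other IUPAC codes are rejected
at parse time so codon translation and transition/transversion
classification stay total functions. GC content excludes N from numerator
and denominator and rounds half-up to two decimals, the precision organelle
papers print.

## Alignment

Two engines sit behind one interface:

* **Affine-gap Smith–Waterman / Needleman–Wunsch** (via Biopython's
  PairwiseAligner) for gene-scale work. Default nucleotide scores are
  +2 / −3 with gap open −5 and extend −2 (a gap of length k costs
  5 + 2k) — a BLASTN-like scheme, since the identity figures this kind of
  comparison is judged against historically come from BLASTN. Protein-level
  comparisons use identity scoring (+1/−1, gaps −2/−1), adequate for close
  homologs and p-distances.
* **Unit-cost edit-distance alignment** (edlib) wherever a short query must
  be located in a whole genome (ORF presence calls, closing inter-anchor
  gaps in collinearity chains). This is exact under unit costs and orders
  of magnitude faster than quadratic DP at genome scale.

Identity is always match columns over all alignment columns, gaps
included — the strictest common convention, monotone under added gaps.
Tie-breaking among co-optimal alignments follows the engine's deterministic
enumeration order; scores are tie-break-independent and are what the
brute-force equivalence tests assert.

In chimera detection, a Smith–Waterman hit is trimmed to its
maximal-identity core before thresholding: alignment columns are rescored
match +1 / mismatch-or-gap −2 and the maximum-scoring contiguous run is
kept (Kadane's rule). Without this, two sequences of similar base
composition can drag low-identity flanks into a hit and blur the fragment
boundaries.

## ORF screen

ORFs run from ATG to the first in-frame stop under the standard genetic
code (plant mitochondria use it; start-codon plasticity and RNA editing are
out of scope). For each (stop, frame) only the longest ATG-initiated ORF is
reported, the convention of standard ORF inventories. The default floor of
101 aa operationalizes "longer than 100 amino acids". Specificity: an ORF
is *present* in a target genome when its best edit-distance placement
(either strand, doubled target) aligns ≥ 90% of its bases at ≥ 95%
identity, and *absent* otherwise; the thresholds are this package's own,
exposed in configuration, since no standard cutoff exists. They sit well
below the ~99% identity of shared genes between closely related mitotypes
and well above the ~70% best placements of genuinely novel ORFs, so the
verdict is insensitive to their exact values across a wide band.

## Transmembrane prediction

A deliberately simple, fully reproducible predictor: Kyte–Doolittle
hydropathy averaged over a 19-residue window, threshold 1.6 — the canonical
published choice for membrane-helix detection. Windows above threshold mark
their full 19 residues; overlapping marks merge, runs separated by fewer
than 5 residues merge (one polar residue should not split a helix), and
segments shorter than 19 residues are dropped. This is not an HMM topology
model: orientation is not predicted, and segment counts for real proteins
will not always match HMM-based tools. The candidate screen only consumes
"has ≥ 1 segment", which is robust to that difference.

## Candidate ranking

Tiering is conjunctive and deterministic: *candidate* = specific AND ≥ 1 TM
segment AND ≥ 1 chimera hit; *supporting* = specific AND (TM OR chimera);
otherwise *excluded*. Chimera hits require ≥ 100 aligned bp at ≥ 90%
identity against an annotated maintainer CDS (the core set is all of them,
not just the atp/cox families, so unexpected chimeras are not missed); an
ORF whose best hit covers ≥ 80% of it at ≥ 95% identity is a relocated gene
copy, not a chimera. Origin assignment uses exact full-length string search
(both strands, doubled circular parents), donor checked first; *recombinant*
requires a donor prefix and recipient suffix (or vice versa), each ≥ 20 nt,
that jointly reconstruct the ORF.

## Variant comparison

Orthologs pair by gene name across annotation sets; unmatched genes are
reported as presence/absence (the cox2-2 pattern). Each mismatch column of
the global alignment becomes a SNP with codon context taken from the
reference CDS; codons hit more than once are classified jointly from the
full alternate codon. Transitions are purine↔purine or
pyrimidine↔pyrimidine by the standard definition. Gap runs become indel
records; a multiple-of-3 length is in-frame and reported in amino acids.
Whole-genome summaries count substitution columns and gap runs inside
collinearity blocks, with gap lengths binned at the 1–5 bp microindel class.

## Repeats and subgenomes

Exact maximal repeated pairs are found by 31-mer seeding and bidirectional
extension on the doubled sequence; every exact repeat ≥ 500 bp (the default
floor) contains a shared 31-mer, so the seed-and-extend search is complete,
and every reported pair re-verifies by direct substring comparison. A
near-exact mode is not needed for the study conditions and is left to the
alignment stages. For a *direct* repeat on a circle of length L,
intramolecular recombination excises circles of (pos_b − pos_a) and
L − (pos_b − pos_a) bp, each keeping one repeat copy — the two sizes always
sum to L, which is the property asserted. Inverted repeats mediate
inversions, not excisions, and raise an error.

## Collinearity

Anchors are maximal runs of k-mers (k = 31) unique in both genomes, both
strands. Chains extend while anchors stay collinear on one strand with
gaps ≤ `max_gap` on both genomes (bounded anchor overlap around indels is
trimmed). Inter-anchor gaps are closed with unit-cost global alignment so
blocks carry exact column statistics; a gap that does not actually align
(closed identity < 70% over ≥ 50 bp, or a > 200 bp size imbalance) splits
the block instead, so coverage — the fraction of the query inside blocks —
behaves like a union of local alignment hits rather than chain spans. The
library default `max_gap` is 2 kb; the pipeline raises it to 12 kb for
mitochondrial comparisons because multi-kb repeats create anchor deserts
(no unique k-mers inside a repeat) that a chain must bridge to report the
repeat region as aligned.

## Phylogenetics

p-distance (differing columns over all columns, gaps count) on globally
aligned pairs feeds Saitou–Nei neighbor joining with lowest-index
tie-breaking. The final three nodes join at a trifurcating root, branch
lengths print at 6 decimals, and negative NJ estimates clamp to zero with a
flag. NJ provably recovers additive matrices, which is the property the
tests fuzz over random trees of 4–8 taxa. Only topology is meant to carry
scientific weight here.

## Synthetic data

The generator builds the study conditions of an alloplasmic CMS system:

* **Recipient/maintainer**: a 221,862 bp circular mitogenome carrying a
  34-gene set with realistic names and sizes (atp/cox/nad/ccm/rps/rpl
  families, two-exon rps3, one recipient-private gene cox2-2).
* **Donor**: 240,024 bp, same genes in the same order (minus cox2-2) on a
  novel intergenic backbone, plus: 26 coding SNPs in 12 genes
  (10 synonymous / 16 non-synonymous, 18 transitions — transcribed
  row-by-row from the study system's variant table), 4 private SNPs in
  genes the mosaic later takes from the recipient, a 33 bp in-frame rps3
  insertion, four long repeats (9432 / 7383 / 2427 bp inverted, 1592 bp
  direct), and 16 donor-specific ORFs with engineered TM stretches
  (11 ORFs, counts 1–6) and chimeric fragments (atp8 175 bp and cox1
  133 bp at ~98% identity) in the three ORFs named orf224 / orf309 /
  orf346, with fixed intergenic context (orf346 ends 103 bp before nad3;
  ccmB starts 217 bp after orf224).
* **CMS mosaic**: donor-majority (90% by default) with three recipient
  blocks spliced in at the midpoints of variant-free shared genes —
  homologous junctions, the way fused-protoplast mitochondria actually
  recombine — so splices are seamless and one block carries cox2-2.

Exactness of the planted truth is engineered, not hoped for: intergenic
filler uses a hydrophilic codon alphabet that cannot spell ATG in any
reading frame of either strand; every element boundary carries a six-frame
stop cassette; random backbone segments are "sterilized" by injecting stop
codons into any chance ATG-run longer than 80 codons (open-ended runs
included); repeat copies get distinct single-base guards so maximal exact
extension stops at exactly the planted length; and the truth table takes
its expected ORF names from an actual caller pass over the finished genome.
The generator raises rather than emitting a genome that violates its own
bookkeeping. Whole-genome GC is tuned to organelle-realistic ~45% through
a 0.44 backbone GC.

What the generator does **not** emulate, and what passing tests therefore
do not show: real parental mitogenomes share most of their backbone (the
real maintainer covers ~86% of the sterile genome; here only the gene set
is shared, ~24%), maintainer genomes carry diverged homologs of the
candidate ORFs (orf222/orf286/orf322-style, 88–96% similar) which the
presence thresholds would have to separate, real repeats have diverged
copies, real gene density and tRNA/rRNA content are higher, and real ORF
inventories include start-codon and editing ambiguity. The accession-based
test exists precisely because synthetic recovery cannot stand in for those
conditions.

The chloroplast-style pair is simpler: one 153,449 bp random genome plus a
copy carrying 60 substitutions and 50 indels of 1–5 bp, spaced ≥ 120 bp
apart so each planted event is recovered as exactly one alignment event.

## Sizes and determinism

Default genome sizes mirror the study system (222–253 kb mitogenomes,
153 kb chloroplasts); the full simulate-and-screen cycle runs in about two
minutes on one core, and the test suite uses a scaled-down trio (62/72 kb,
4 ORFs, 2 repeats) for its fast paths. All randomness flows from one
numpy Generator seeded by the user; the same seed yields byte-identical
genomes. Reported percentages round at 2 decimals, identities in tables at
1–2 decimals; alignment scores are integers throughout.

## Known limitations

Presence calling measures sequence similarity, not ORF integrity — a
frameshifted but sequence-similar counterpart still counts as "present".
The TM predictor has no orientation model. The collinearity chainer is
greedy (last-chain-only) and can fragment blocks in heavily rearranged
genomes; coverage tolerances absorb this at organelle scale. Origin
assignment demands perfect identity, as the study design warrants, and
will call "novel" for a single sequencing error. The subgenome model
predicts sizes from one recombination event only; nested repeat
configurations produce circle inventories beyond its scope.
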