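# Methods

## The problem

Human ribosomal DNA is organized as tandem arrays of ~45-kb repeat
units on the five acrocentric chromosomes, a few hundred copies per
genome. The intergenic spacer of some units carries a complete open
reading frame encoded on the strand opposite the pre-rRNA — a
190-residue, strongly hydrophobic protein whose coding span is 573 nt
including the stop codon. Other units carry disabled alleles: 5-bp
deletions and 5- or 10-bp insertions that shift the frame and truncate
the predicted product, a 15-bp in-frame insertion that adds one unit of
a hydrophobic pentapeptide repeat, and recurrent point substitutions.
Because the locus sits inside a high-copy tandem repeat, surveying it
requires repeat-aware methods: per-unit screening in assemblies, and
coverage-normalized read counting in unassembled long-read data.

## Per-unit classification

The reference ORF is aligned against both strands of each unit by
edit-distance-optimal infix alignment (edlib). A unit reports
`NO_LOCUS` when the best alignment falls below 80% identity or covers
less than half the reference (both configurable). Otherwise the
alignment is left-normalized (indels shifted maximally left, making
their placement in homopolymers deterministic) and summarized:

* `net_indel_nt` = inserted − deleted columns. Its residue mod 3 fully
  determines `FRAMESHIFT` (≢ 0) vs `FRAME_PRESERVING_INDEL` (≡ 0, ≠ 0).
* The start-codon check is anchored to the alignment column of the
  reference ATG, not to any ATG in the locus — a unit whose locus is
  intact except for a start-site loss must not be counted complete.
* The predicted product is obtained by translating the unit's own
  sequence from that anchor to the first stop, reading up to 600 nt
  beyond the locus so delayed stops are found. `COMPLETE` requires
  net indel 0, the anchored ATG, and a full-length (190-aa) product.
* Loci with intact frame but a lost start or premature stop are
  reported as `DISRUPTED`, a separate census column. The four
  indel-driven statuses cannot represent this case, and distinguishing
  it matters: start-site-loss alleles are exactly what separates
  near-complete homologs from functional copies.

Identity is always matches / alignment columns with gap columns in the
denominator, and `N`/`X` never count as matches. Predicted masses use
average (not monoisotopic) residue weights, the convention relevant to
comparing against gel bands.

## Read-level detection

Three staged gates, evaluated per read with one best hit per read:

1. *Translated search.* The read region located by a bounded
   edit-distance pre-scan (reference ORF vs both read strands, edit
   budget 40% — generous enough that nothing able to reach the later
   gates is skipped) is translated in all six frames and aligned to the
   reference protein by Smith–Waterman (BLOSUM62, gap open −11,
   extend −1). Retained iff identity > 85% and aligned length > 150 aa
   (both strict).
2. *Nucleotide re-match.* The reference ORF is re-aligned to the read
   region in nucleotide space; the matched region is extracted in
   reference orientation iff identity > 85% (strict) and the aligned
   reference span is ≥ 550 bp (inclusive; the span is measured on the
   reference).
3. *ORF check.* The extracted region must contain an ATG-initiated ORF
   of ≥ 180 nt ending at a stop codon. Open-ended ATG runs are never
   reported: a truncated allele must show its premature stop.

The strict/inclusive split follows the wording of the thresholds
("over 85%", "over 150 aa" vs "85% identity and 550 bp"); every gate is
configurable and echoed into output JSON. Consequences worth knowing:
a single indel sequencing error inside the ORF truncates the translated
match at that point (exactly as it would under a translated BLAST
search), and a read must effectively contain the ORF end-to-end to pass
stage 3, since the engineered reference has no internal methionine.

## Copy-number estimation

Haploid coverage = total read bases / genome size (3.1 Gbp for
human-scale data; simulated runs must pass the simulated genome size —
normalization is meaningless otherwise). ORF copies per haploid genome
= stage-3 read count / coverage.

Total rDNA copies: reads are mapped to a *doubled* canonical repeat
unit, so reads spanning the junction of the circular-like tandem array
align contiguously; reads overlapping the ORF locus in either copy at
over 99% identity are counted, each read once, and normalized by
coverage. Any ≥ 1 nt overlap counts (the design quotes no
minimum-overlap clause). Two mapping engines are provided:

* `minimap2` (default): HiFi preset with base-level alignment;
  identity = matches / alignment-block length of the primary mapping.
  This is the approximate-mapper identity the survey design calls for
  and is fast enough for whole read sets.
* `edlib`: the whole read is embedded in the doubled reference by
  bounded edit distance; identity = 1 − editDistance / readLength.
  Stricter at array edges (no soft-clipping); used in the test suite as
  an independent cross-check of the minimap2 route.

Because a read must contain 550+ nt of the locus to count as an ORF
read but any 1-nt overlap counts as an rDNA read, the estimated
fraction carries a small, read-length-dependent downward bias
(~(L−573)/(L+573) ≈ 0.93 at 15-kb reads); at the stated tolerances this
is immaterial, and it mirrors the behavior of the original gates.

## Allele spectrum

Extracted alleles differ from the reference by a handful of edits, so a
reference-anchored star alignment (each allele pairwise-global-aligned
to the reference; insertion columns keyed to the preceding reference
position; indels left-normalized) is exact and replaces a progressive
MSA. Indel events present in ≤ 5% of rows are treated as residual
sequencing errors and reverted (insertions dropped, deletions restored
to the reference base); the operation is idempotent and monotone in the
threshold, and substitution columns are never touched. The 5% default
is a deliberately low, configurable cutoff — the common 15-bp in-frame
insertion segregating at tens of percent must survive it. Classes:
any surviving in-frame indel ⇒ `frame_preserving_indel`; otherwise by
substitution count (exact / one / two / two-plus); frameshift-indel
rows get their own bucket rather than contaminating the others.

## Protein characterization

* Kyte–Doolittle hydropathy; the overall index is the mean per-residue
  value mapped linearly from [−4.5, +4.5] (Arg…Ile) onto [0, 1]. The
  0–1 scale is conventional in this literature but the mapping is
  rarely stated; the linear map is the single most defensible choice,
  is printed in every report, and is configurable. Profiles are
  valid-window means (window 9 by default; the window does not affect
  the overall index).
* Charged residues: positives R/K (histidine excluded by default, flag
  to include — both conventions are defensible and the census reports
  which was used), negatives D/E.
* Motifs: degenerate patterns over single letters and bracketed classes
  (default `I[VL]LY[CR]`), all overlapping occurrences reported.
* Amphipathic segmentation: maximal runs of the scaled profile above or
  below a threshold (default 0.7).

## The synthetic data generator

The generator is first-class, tested code; its defaults *are* the study
conditions.

**Reference ORF.** The 190-aa protein is engineered to the documented
architecture: hydrophobic residues 1–10 and 110–190; a relatively
hydrophilic core at 11–109 (standing in for the Alu-derived insertion
of the real protein) holding 13 of 18 positive and 3 of 6 negative
charges; three pentapeptide motif units (IVLYC, IVLYR, ILLYC) in the
C-terminal arm. The neutral core filler is a deterministic mix of two
diverse residue palettes solved so the overall scaled hydropathy index
lands on 0.708 (quantization < 0.002); diversity matters, because a
low-complexity core would translate to a similar protein after a
frameshift and blur the signal every stage relies on. Fixed codon
choices plant the reference bases of the recurrent substitution
spectrum (T at nt 32, G at 385, C at 400, so L11S, V129L and L134V
arise from single base changes). Methionine occurs only at position 1,
and codon choice is re-drawn until (a) the 573-nt construct contains
exactly one ≥ 180-nt ORF on either strand and (b) both shifted frames
downstream of the frameshift edit point stop within 65 codons, so
frameshift alleles are guaranteed the premature truncations they
emulate. Mean residue mass comes out near real-protein values
(≈ 21.6 kDa for the full product; ≈ 15 kDa for the 5-bp-deletion
truncation).

**Arrays.** All units of an array share one seeded-random ~50% GC
spacer backbone with the ORF embedded antisense ~30% into the unit,
mirroring the > 99% identity of real repeat units; only the planted
allele differs per unit. The survey-scale default plan has 219 units on
five chromosomes with 43 complete (39 consecutive on chr21, two on
chr14, one each on chr13/chr22), one chr15 unit carrying the 15-bp
in-frame insertion plus an L>S variant, and the remainder frameshifted
(5-bp deletions dominating, 5-bp insertions on chr14/chr22, one 10-bp
insertion). Complete units carry the L>V substitution except the chr22
copy.

**Reads.** HiFi-like: log-normal lengths around 15 kb (truncated to
1–32 kb), uniform starts, random strands, 0.05% substitutions and
0.02% single-base indels with a ×5 rate multiplier inside homopolymer
runs ≥ 3 — the published accuracy class of HiFi consensus reads.
Simulated genomes place the array between two random background flanks
(default 310 kb each, giving 5.0 Mb at 20-kb units).

**Allele samples.** A 200-record population with 13% exact, 25%
one-change (96% of them the modal G>C at nt 385), 19% two-or-more
changes drawn from the recurrent-position spectrum, 43% frame-preserving
insertions, plus a 2% sprinkle of private single-base homopolymer
indels to exercise the rare-indel filter.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: real intergenic-spacer sequence content
(Alu/repeat structure, promoter/ETS architecture, k-mer composition),
inter-unit divergence outside the ORF locus, diploidy and haplotype
structure, chimeric or low-quality reads, and basecall-quality
correlation with errors. Results on synthetic arrays validate the
*logic* of the pipeline (classification, gating, normalization), not
mapper behavior on genuinely repetitive human backgrounds.

## Problem sizes and numerical choices

Survey-scale runs use 20-kb units (219 units ≈ 4.4 Mb of array in a
5-Mb genome) at 20× coverage — the unit length is scaled down from the
real ~45 kb so that a full multi-replicate recovery experiment runs in
minutes on one CPU while preserving every length relation that matters
(reads ≪ unit, locus ≪ read). Copy-number recovery is assessed as the
mean over seeded replicates (five in the test suite, three in the
acceptance script). Alignment tie-breaks follow the underlying engines
(edlib may split tie-equivalent gap runs; left-normalization restores
determinism where positions are reported). All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; every
emitted file is byte-reproducible under a fixed seed.

## Known limitations

* Equivalence with the external tools the gates paraphrase (translated
  BLAST, MUMmer, ORFfinder, MashMap) is claimed at the
  threshold-decision level, not alignment-by-alignment.
* Nucleotide alignment is unit-cost edit distance, not an affine-gap
  match/mismatch scheme; in the > 80%-identity regime the pipeline
  operates in, identity-threshold decisions coincide, but alignments of
  diverged pairs may differ.
* The edlib copy-number engine requires whole-read embedding and so
  undercounts reads straddling an array edge; the minimap2 engine
  soft-clips instead. Both are exposed; defaults favor the mapper.
* Per-chromosome attribution is only possible from assembled units;
  read-based estimates are genome-wide by construction.
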