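# Methods

## Model and coordinate conventions

All internal coordinates are 0-based half-open genomic intervals; HGVS and
VCF I/O are 1-based; BED is 0-based half-open. Splice reasoning happens on
the transcript-orientation sequence: for a minus-strand gene that is the
reverse complement of the genomic sequence, and "downstream exon" means the
lower-coordinate exon. Intronic positions use the HGVS acceptor-side
convention: offset *N* is the 1-based distance from the first base of the
downstream exon, so offset 1 is the terminal G of the acceptor AG.

The analysis gene is minus-strand by default, mirroring the antisense
transcription of the real locus; a plus-strand mirror is constructed in the
test suite and must yield identical offsets (strand invariance).

### Branchpoint scanning

Candidate branchpoints are the adenosines 18–44 nt upstream of the 3′ splice
site — the standard positioning of human branchpoints. Each candidate A is
scored against a fixed hand-weighted pyrimidine-context consensus:
0.25 for a pyrimidine two bases 5′ of the A, 0.5 for a U (T) immediately 5′,
0.25 for a pyrimidine immediately 3′; scores lie in [0, 1]. Candidates are
ranked by score, ties broken by proximity to the 3′ splice site — a
deterministic, documented rule. This is intentionally *not* a trained
branchpoint predictor: the biological claim being tested rests on the
identity and position of a single A, which the consensus captures; package
users needing genome-wide branchpoint calls should use a dedicated predictor.

A variant disrupts splicing iff it converts the top-ranked candidate's A to
a non-A base. The cryptic acceptor is the nearest AG dinucleotide strictly
5′ of the disrupted branchpoint; the retained segment is every intronic base
3′ of that AG through the intron end, so `retained_len = acceptor_offset − 1`.
Whether the cell selects that AG via an alternative branchpoint or by simple
proximity is not resolvable from the data this package models; we implement
nearest-upstream-AG and report the branchpoint-to-acceptor spacing (which,
at 6 nt in the reference geometry, is far below typical acceptor spacing)
rather than filtering on it, leaving any spacing-based filter to the caller.
The alternative branchpoint, when one exists, is reported as an annotation
only. On the default synthetic intron the scan yields: branchpoint A at
offset 34, cryptic AG ending at offset 40, retained segment 39 nt.

### Quantification regions

The regions are the two exons flanking the focal intron, the full intron,
the short-transcript window (the intronic bases abutting the downstream
exon), the remainder of the intron, the gene span and the paralog span. The
window length defaults to the predicted retained-segment length (39 nt in the
reference geometry) because that is the mechanistic quantity; it is
overridable since descriptions of this window in the field vary between
"~40 bp" and the exact retained length. Window and remainder always
partition the intron exactly.

### Coverage and association

Regional mean depth is a per-base pileup average under a samtools-style
filter (`depth_profile`: MAPQ ≥ 5, base quality ≥ 20 where qualities exist,
excluding unmapped/secondary/QC-fail/duplicate records). Read retention
upstream of depth uses a distinct profile (`retention_profile`: MAPQ ≥ 40,
primary records only); the two filters serve different purposes and are
deliberately not conflated. Normalized coverage is
`mean_depth / (total_mapped_reads / 10⁶)`; the denominator counts primary
mapped reads genome-wide (supplementary and secondary records excluded),
with the profile-filtered alternative exposed as a parameter. Depth counts
deleted bases inside an aligned block as covered (span dialect) because the
synthetic alignments carry no indels; an aligned-base dialect is available
when records are built from real CIGARs.

The genotype association regresses normalized coverage on genotype. With
more than 5 homozygous-risk samples the predictor is the three-level
risk-allele dosage {0, 1, 2}; otherwise the sparse GG group is pooled with
GT and the predictor is the binary carrier indicator. The threshold of 5
follows the grouping rule of the study design this package models. The
binary-grouping regression is algebraically identical to the pooled-variance
two-sample t test (asserted in the test suite). A response with zero
variance is reported as slope 0, r² 0, p 1 rather than an error.

### Read-level analyses

Allele assignment reads the query base mapped onto the variant site;
reads not covering the site are `uncovered`, covered bases matching neither
allele are `other` (low-quality bases at the site can be excluded via a
base-quality floor and are reported with their quality so exclusions are
countable). Haplotype purity is the risk fraction among covered
retention-class reads with a Clopper–Pearson interval.

The allele-swap control flips risk↔nonrisk at the variant position inside
each read sequence and re-assigns original and flipped reads to gene vs
paralog by full local dynamic-programming alignment (match +1, mismatch −1,
gap −2, via Biopython's PairwiseAligner; verified against a hand-written
Smith–Waterman oracle). Desk-scale inputs make exhaustive alignment
affordable and keep the control free of external aligner configuration.
Ties are flagged ambiguous and excluded from the concordance rate; any
concordance below 1 produces an explicit warning that assignment is
variant-driven.

Isoform classification is interval arithmetic over the region set:
full retention = ≥ 90% of the intron covered plus downstream-exon bases;
partial retention = ≥ 80% of the short window covered plus downstream-exon
bases with < 90% of the intron remainder; canonical = junction-spanning with
≤ 2 intronic bases; anything else ambiguous. The 0.8 / 0.9 / 2-base
thresholds are package choices (exposed as parameters) selected to make the
classes mutually exclusive on error-free truth reads; the test suite holds
classification to exact agreement with an independent interval oracle.

Barcode demultiplexing assigns a read to the unique whitelist barcode within
one mismatch (parameter); reads matching none, or two or more at equal
distance, land in an `unassigned` bucket that is reported, never dropped.
The methylation contrast is a 2×2 allele × methylated Fisher exact test with
per-allele fractions; a missing allele yields fractions plus an explicit
undefined-test flag.

## Synthetic data: what it emulates, and what it does not

The generator builds a ~560-bp three-exon gene (exons 120/150/100 nt,
introns 90/100 nt) on a minus strand with a pseudogene copy 400 bp
downstream at 96% identity (realized identity held within ±1 percentage
point by substituting an exact count of positions; a fixed paralog-private
base marks the position homologous to the variant, and every 250-nt window
overlapping the focal intron carries ≥ 3 distinguishing substitutions so
intron-spanning reads are assignable). The focal intron's 3′ tail encodes
the reference geometry exactly: branchpoint A at offset 34 in a perfect
pyrimidine context, cryptic AG at offsets 41/40, no other window adenosine,
terminal AG. The reference sequence carries the *nonrisk* allele (the
branchpoint A) so that branchpoint enumeration on the reference sees the
intact motif; the VCF presents nonrisk ref / risk alt. On the sense strand
the risk allele is G and the nonrisk allele is T, matching the field's
naming for this locus.

Cohort reads: per sample, each read picks a haplotype (uniformly between the
two), then an isoform conditional on the haplotype's allele — risk-allele
transcripts are partial-retention with p = 0.15, full-retention with
p = 0.05, canonical otherwise; nonrisk transcripts are canonical only. The
true per-allele retention fractions in any tissue are not established, so
these defaults are power-analysis placeholders, not field estimates. The
partial isoform is constructed *by calling the splice module* on the locus
variant, so generator and analyzer share one geometry by construction (and a
test asserts it). Long mode emits 3′-anchored reads with Poisson-like 5′
truncation at 0.2 events/kb — retention is detected by 3′-anchored coverage,
so the generator produces the matching 3′ bias; short mode emits
normal-length fragments (300 ± 50 nt). Errors are substitutions only at a
default 1% — allele assignment at a point site is the quantity under test,
and indel realism is out of scope. Default cohort: 1 GG, 4 GT, 3 TT samples
at 300 reads each, the genotype layout of the smallest real cohort design
this emulates, at a depth that keeps hundreds of Monte-Carlo replicates
affordable. Each read's truth (sample, haplotype, isoform, 16-nt cell
barcode) travels in a structured read name and a truth table; truth SAM
alignments are error-free, primary, MAPQ 60, so the pipeline runs without an
external aligner. Reads can be generated without base sequences
(`with_sequences=False`) for coverage-only analyses; coordinates come from a
dedicated RNG substream and are identical either way.

What the generator does **not** model: realistic ONT error profiles, indels,
basecalling artifacts, capped/uncapped transcript distinctions, expression
level differences between tissues, or linkage beyond the single variant
site. Passing tests therefore demonstrate the correctness of the analysis
logic under the stated generative assumptions, not robustness to real ONT
noise or mapping ambiguity beyond the modeled paralog.

Enzyme activity: `y = α + β·g + N(0, σ²)` with α = 10 µmol L⁻¹ h⁻¹ (a
typical normal-range activity on dried blood spots), β = −0.449 per risk
allele, group sizes 97 TT / 99 GT / 9 GG, and σ calibrated by inverting the
closed-form OLS slope standard error so that se(β̂) = 0.205 at those group
sizes (σ = 0.205·√Sxx ≈ 1.69). Methylation: Bernoulli per-read 5mC with
p = 0.9 (risk) / 0.1 (nonrisk) — high but imperfect separation, as per-read
calls are noisy even when the underlying allele state is binary.

## Numerical and design choices

- Every random draw flows from `numpy.random.default_rng`; the pipeline
  splits one seed into stage-scoped substreams so stages are independently
  reproducible and a fixed config+seed yields a byte-identical summary.
- Degenerate fits (constant response) report slope 0, r² 0, p 1; degenerate
  predictors (single genotype level) raise "no contrast", which the pipeline
  records per region and survives.
- Fisher tests with an all-zero margin are flagged undefined rather than
  given an arbitrary p.
- The null-distribution check of the association machinery regresses
  normalized coverage of an *expressed* region (the downstream exon) on
  genotype in cohorts with all retention rates zero. Intron regions are
  identically zero in such cohorts, which makes their regression degenerate
  by design (p = 1); only an expressed region has the continuous sampling
  noise a type-I-error measurement needs.
- Monte-Carlo suite sizes (500 activity cohorts, 500 null cohorts, 100 power
  cohorts, 50 swap-control seeds, 200 pileup-oracle instances) balance
  statistical resolution against a test suite that completes in well under a
  minute.

## Known limitations

- Single-isoform gene models; no overlapping genes; one variant per run.
- The HGVS parser covers exactly the acceptor-side intronic SNV pattern the
  analysis needs (`c.<pos>-<offset><ref>><alt>`), not the HGVS grammar.
- The allele-swap control is O(read × reference) dynamic programming —
  appropriate for locus-scale references, not genomes; the pipeline
  subsamples to 50 covering reads by default.
- The cryptic-acceptor rule is purely sequence-based; it does not model
  acceptor strength, polypyrimidine-tract quality, or spacing constraints.
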