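# branchretain

Variant-to-function analysis of a branchpoint-disrupting intronic SNV in a
gene that shares ~96% sequence identity with a downstream pseudogene.

The scientific setting: a common noncoding risk variant sits 34 bp upstream of
an exon, inside the branchpoint motif of the preceding intron, in a gene
transcribed from the antisense strand. On the transcript, the nonrisk allele
is the branchpoint adenosine itself; the risk allele replaces it with a C.
With the branchpoint gone, splicing either fails outright (full intron
retention) or re-routes through the nearest upstream AG dinucleotide — a
cryptic 3′ splice site ending 6 nt upstream of the variant — leaving the
3′-terminal 39 nt of the intron in the mature, polyadenylated transcript
(partial retention). Retention transcripts arise exclusively from the risk
haplotype, the risk allele is CpG-methylated while the nonrisk allele is not,
and the downstream enzyme activity falls linearly with risk-allele dosage.

`branchretain` implements every computational stage of that analysis as a
reusable library + CLI, and ships a synthetic-data generator that emulates the
full study design so the pipeline is testable end to end without any
controlled-access data:

- **gene_model** — strand-aware coordinates, HGVS-style intronic offsets
  (`c.1225-34C>A` → offset 34), and the quantification regions (flanking
  exons, full intron, the short-transcript window abutting the downstream
  exon, the remainder of the intron, gene, paralog), writable as BED.
- **splice_model** — rule-based branchpoint enumeration in the 18–44 nt
  window (consensus-weighted scoring of each candidate A), disruption calls,
  nearest-upstream-AG cryptic-acceptor scanning, and predicted isoform models
  (canonical / partial / full retention) as GTF.
- **coverage_quant** — regional mean depth under samtools-style filters
  (MAPQ ≥ 5, base quality ≥ 20, excluding unmapped/secondary/QC-fail/
  duplicate), per-million normalization `mean_depth / (mapped_reads / 10⁶)`,
  and the genotype association: dosage regression when >5 homozygous-risk
  samples are available, otherwise risk-carriers-vs-noncarriers.
- **read_analysis** — allele-of-origin assignment at the variant site,
  haplotype purity of retention reads with exact binomial CI, the allele-swap
  remapping control (flip the variant base in every read, re-assign
  gene vs pseudogene by alignment score, report concordance), isoform
  classification, one-mismatch barcode demultiplexing, per-allele methylation
  contrast (Fisher exact).
- **stats** — unadjusted OLS on dosage, directional two-group tests, exact
  2×2 tests.
- **synthetic_data** — paralog-pair reference construction, diploid read
  cohorts with allele-conditional retention, methylation calls, and the
  enzyme-activity cohort `y = α + β·g + ε` with β = −0.449 per risk allele
  and noise calibrated so the analytic slope s.e. at group sizes 97/99/9 is
  0.205.

## Worked example

Run the whole pipeline on a default synthetic cohort (1 GG, 4 GT, 3 TT
samples, 300 long reads each):

```sh
branchretain run-all --outdir run1 --seed 1
```

Key entries of the printed `summary.json`:

```json
"splice": {
  "variant_offset": 34, "branchpoint_offset": 34, "disrupted": true,
  "cryptic_acceptor_offset": 40, "bp_to_acceptor_gap": 6, "retained_len": 39
},
"association": { "intron_short_window": {
  "grouping": "binary", "slope": 120102.56, "p": 0.0173 } },
"haplotype_purity": { "fraction_risk": 0.9944, "n_covered": 178 },
"swap_control": { "concordance": 1.0, "n_evaluated": 49 },
"methylation": { "fractions": {"G": 0.912, "T": 0.122}, "p": 7.6e-157 },
"gcase_regression": { "slope": -0.402, "se": 0.222, "p": 0.072 }
```

Reading: the variant lands exactly on the top-ranked branchpoint A at
intronic offset 34; disrupting it selects the cryptic AG ending at offset 40
(6 nt upstream of the variant), predicting a 39-nt retained segment.
Normalized coverage of that window is significantly higher in risk-allele
carriers than in TT samples; 99.4% of retention-class reads carry the risk
allele (the remainder are sequencing-error bases at the site); flipping the
variant base changes no read's gene/pseudogene assignment, so the coverage
signal is not a mapping artifact; methylation is present on the risk allele
and lost on the nonrisk allele; and a single simulated activity cohort
recovers a negative dosage slope near the generative −0.449 (any one cohort's
estimate is noisy — the recovery test below averages 500).

Individual stages are available as `branchretain simulate | splice-scan |
quantify | regress | demux | meth`, and as plain library calls.

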