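"""Synthetic locus, cohort and phenotype generator.

Emulates the study design the analysis modules expect, without any external
data: a minus-strand gene whose focal intron carries a branchpoint adenosine
34 nt upstream of the downstream exon, a cryptic AG acceptor ending 6 nt
further upstream, and a downstream pseudogene copy at ~96% identity; diploid
cohorts whose risk-haplotype transcripts show partial and full retention of
that intron; per-read CpG methylation linked to the variant allele; and an
enzyme-activity phenotype with a linear risk-allele dosage effect.

Sense-strand alleles follow the field's naming for this locus: G is the risk
allele and T the nonrisk allele. The reference sequence here carries the
nonrisk base (transcript-orientation branchpoint A) so branchpoint enumeration
on the reference sees the intact motif; the VCF therefore lists T as REF and
G as ALT. On the transcript (antisense) level the risk allele is C and the
nonrisk allele is the branchpoint A.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .gene_model import (
    GeneModel,
    IntronOffset,
    VariantSite,
    build_region_set,
    reverse_complement,
    write_bed,
    write_gtf,
)
from . import splice_model

RISK_ALLELE = "G"  # sense strand
NONRISK_ALLELE = "T"

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

# Focal-intron 3' tail, transcript orientation, offsets 44..1. Encodes the
# branchpoint A at offset 34 inside a uUuAu-like context (score 1.0), the
# cryptic AG at offsets 41/40 (gap 6 from the branchpoint, retained segment
# 39 nt), no other adenosine in the 18-44 search window, and the terminal
# acceptor AG.
_FOCAL_TAIL = (
    "CCC"      # 44..42
    "AG"       # 41..40  cryptic acceptor
    "CTCTT"    # 39..35
    "A"        # 34      branchpoint
    "T"        # 33
    "CTTCCTTCCTTCCTC"  # 32..18
    "TCCTTCTCCTTCCTC"  # 17..3
    "AG"       # 2..1    canonical acceptor
)
assert len(_FOCAL_TAIL) == 44

FOCAL_VARIANT_OFFSET = 34  # branchpoint position, HGVS-style intronic offset


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


@dataclass
class SyntheticLocus:
    """A two-paralog chromosome with its gene model and provenance."""

    chrom: str
    chrom_seq: str
    gene: GeneModel  # .paralog holds the pseudogene model
    identity: float  # realized gene/pseudogene identity
    distinguishing_sites: list[int]  # genomic positions where paralogs differ

    def write_fasta(self, path: str, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.chrom_seq), line_width):
                fh.write(self.chrom_seq[i : i + line_width] + "\n")

    def gene_region_seq(self) -> str:
        lo, hi = self.gene.span
        return self.chrom_seq[lo:hi]

    def paralog_region_seq(self) -> str:
        lo, hi = self.gene.paralog.span
        return self.chrom_seq[lo:hi]

    def focal_intron_seq(self) -> str:
        return self.gene.intron_seq(self.chrom_seq, self.gene.focal_intron())

    def splice_call(self) -> splice_model.SpliceCall:
        """Branchpoint call for the locus variant on its focal intron."""
        off = self.gene.genomic_to_intron_offset(
            self.gene.focal_intron(), self.gene.variant_site.pos
        )
        ref_t, alt_t = self.variant_transcript_alleles()
        return splice_model.call_splice_disruption(
            self.focal_intron_seq(), off.offset, ref_t, alt_t
        )

    def variant_transcript_alleles(self) -> tuple[str, str]:
        v = self.gene.variant_site
        if self.gene.strand == "-":
            return reverse_complement(v.ref), reverse_complement(v.alt)
        return v.ref, v.alt


DEFAULT_EXON_LENGTHS = (120, 150, 100)  # transcript order
DEFAULT_INTRON_LENGTHS = (90, 100)
DEFAULT_FOCAL_INTRON_INDEX = 1


def build_paralog_pair(
    exon_lengths: tuple[int, ...] = DEFAULT_EXON_LENGTHS,
    intron_lengths: tuple[int, ...] = DEFAULT_INTRON_LENGTHS,
    focal_intron_index: int = DEFAULT_FOCAL_INTRON_INDEX,
    target_identity: float = 0.96,
    strand: str = "-",
    seed: int = 0,
    chrom: str = "chrS",
    flank: int = 300,
    spacer: int = 400,
    min_sites_per_window: int = 3,
    window: int = 250,
) -> SyntheticLocus:
    """Build the gene + downstream pseudogene chromosome.

    The pseudogene is a mutated copy of the gene region at ``target_identity``
    (realized identity within one percentage point), with at least
    ``min_sites_per_window`` paralog-distinguishing substitutions in every
    ``window``-nt window overlapping the focal intron so reads over the intron
    are assignable, and a fixed non-reference base at the position homologous
    to the variant site.
    """
    if not (0.5 < target_identity < 1.0):
        raise ValueError(f"target_identity must be in (0.5, 1), got {target_identity}")
    if len(intron_lengths) != len(exon_lengths) - 1:
        raise ValueError("need exactly one fewer intron than exons")
    if not (0 <= focal_intron_index < len(intron_lengths)):
        raise ValueError("focal_intron_index out of range")
    if intron_lengths[focal_intron_index] < len(_FOCAL_TAIL) + 2:
        raise ValueError(
            f"focal intron must be at least {len(_FOCAL_TAIL) + 2} nt to hold the splice geometry"
        )
    if (1 - target_identity) * window < min_sites_per_window:
        raise ValueError(
            f"target_identity {target_identity} too high to guarantee "
            f"{min_sites_per_window} distinguishing sites per {window}-nt window"
        )
    rng = np.random.default_rng(seed)

    # assemble the gene in transcript order, then lay out genomically
    pieces_t: list[tuple[str, str]] = []  # (kind, seq in transcript orientation)
    for i, elen in enumerate(exon_lengths):
        pieces_t.append(("exon", _random_seq(rng, elen)))
        if i < len(intron_lengths):
            ilen = intron_lengths[i]
            if i == focal_intron_index:
                mid = _random_seq(rng, ilen - 2 - len(_FOCAL_TAIL))
                iseq = "GT" + mid + _FOCAL_TAIL
            else:
                iseq = "GT" + _random_seq(rng, ilen - 4) + "AG"
            pieces_t.append(("intron", iseq))

    gene_t = "".join(seq for _, seq in pieces_t)
    gene_genomic = gene_t if strand == "+" else reverse_complement(gene_t)
    glen = len(gene_genomic)

    gene_start = flank
    gene_end = gene_start + glen

    # exon genomic intervals
    exons: list[tuple[int, int]] = []
    cursor = 0
    for kind, seq in pieces_t:
        if kind == "exon":
            if strand == "+":
                exons.append((gene_start + cursor, gene_start + cursor + len(seq)))
            else:
                exons.append((gene_end - cursor - len(seq), gene_end - cursor))
        cursor += len(seq)
    exons.sort()

    # pseudogene copy, mutated
    # exact substitution count, not per-base Bernoulli: on a short gene the
    # binomial scatter would routinely leave the ±1pp identity band
    q = 1 - target_identity
    para_start = gene_end + spacer
    para = np.frombuffer(gene_genomic.encode(), dtype="S1").astype("U1")
    n_sub = int(round(q * glen))
    for i in rng.choice(glen, size=n_sub, replace=False):
        choices = [b for b in "ACGT" if b != para[i]]
        para[i] = choices[rng.integers(0, 3)]

    model = GeneModel(
        name="GENE", chrom=chrom, strand=strand, exons=exons,
        focal_intron_index=focal_intron_index,
    )
    fs, fe = model.focal_intron()
    variant_pos = model.intron_offset_to_genomic(
        (fs, fe), IntronOffset(FOCAL_VARIANT_OFFSET)
    )
    ref_sense = gene_genomic[variant_pos - gene_start]
    alt_sense = reverse_complement("C") if strand == "-" else "C"  # risk = C on transcript
    model.variant_site = VariantSite(pos=variant_pos, ref=ref_sense, alt=alt_sense)

    # fixed paralog-private base at the variant-homologous position
    vh = variant_pos - gene_start
    para[vh] = "C" if gene_genomic[vh] != "C" else "A"

    # enforce distinguishing-site density over windows touching the focal intron
    gene_arr = np.frombuffer(gene_genomic.encode(), dtype="S1").astype("U1")
    i_lo, i_hi = fs - gene_start, fe - gene_start
    w0 = max(0, i_lo - window + 1)
    for ws in range(w0, min(i_hi, glen - window) + 1):
        sl = slice(ws, ws + window)
        deficit = min_sites_per_window - int((para[sl] != gene_arr[sl]).sum())
        while deficit > 0:
            j = ws + int(rng.integers(0, window))
            if para[j] == gene_arr[j]:
                choices = [b for b in "ACGT" if b != para[j]]
                para[j] = choices[rng.integers(0, 3)]
                deficit -= 1

    para_seq = "".join(para)
    realized = float((np.asarray(list(para_seq)) == gene_arr).mean())
    if abs(realized - target_identity) > 0.01:
        raise ValueError(
            f"realized identity {realized:.4f} outside ±1pp of target {target_identity}"
        )

    paralog = GeneModel(
        name="PSEUDO", chrom=chrom, strand=strand,
        exons=[(s - gene_start + para_start, e - gene_start + para_start) for s, e in exons],
    )
    model.paralog = paralog

    chrom_seq = (
        _random_seq(rng, flank) + gene_genomic + _random_seq(rng, spacer) + para_seq + _random_seq(rng, flank)
    )
    sites = [gene_start + i for i in np.flatnonzero(gene_arr != np.asarray(list(para_seq)))]
    locus = SyntheticLocus(
        chrom=chrom, chrom_seq=chrom_seq, gene=model,
        identity=realized, distinguishing_sites=sites,
    )
    model.validate_splice_sites(chrom_seq)
    return locus


# ---------------------------------------------------------------------------
# cohort reads
# ---------------------------------------------------------------------------

GENOTYPES = ("GG", "GT", "TT")


@dataclass
class CohortSpec:
    """Study conditions for a simulated read cohort."""

    n_per_genotype: dict = field(default_factory=lambda: {"GG": 1, "GT": 4, "TT": 3})
    retention_rates: dict = field(
        default_factory=lambda: {RISK_ALLELE: (0.15, 0.05), NONRISK_ALLELE: (0.0, 0.0)}
    )
    depth_per_sample: int = 300
    read_length_mean: float = 300.0  # short mode fragments
    read_length_sd: float = 50.0
    truncation_per_kb: float = 0.2  # long mode 5' truncation rate
    error_rate: float = 0.01
    min_read_len: int = 50
    seed: int = 0

    def __post_init__(self):
        for allele, (pp, pf) in self.retention_rates.items():
            if pp < 0 or pf < 0 or pp + pf > 1:
                raise ValueError(f"invalid retention rates for {allele}: ({pp}, {pf})")
        if any(n < 0 for n in self.n_per_genotype.values()):
            raise ValueError("negative sample count")


@dataclass
class SimRead:
    """One simulated cDNA read with its generative truth."""

    name: str
    sample: str
    genotype: str
    haplotype: str  # sense-strand allele of the originating haplotype
    isoform: str  # canonical | partial_retention | full_retention
    barcode: str
    chrom: str
    strand: str
    blocks: list  # genomic (start, end) blocks of the alignment
    seq: Optional[str] = None  # transcript-orientation cDNA (no barcode)

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


def make_barcode_whitelist(n: int = 4, length: int = 16, min_dist: int = 5, seed: int = 7) -> list[str]:
    """Random fixed-length barcodes with pairwise Hamming distance >= min_dist."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        cand = _random_seq(rng, length)
        if all(sum(a != b for a, b in zip(cand, w)) >= min_dist for w in out):
            out.append(cand)
    return out


def _transcript_interval_to_blocks(
    blocks: list[tuple[int, int]], strand: str, a: int, b: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval [a, b) onto genomic blocks."""
    total = sum(e - s for s, e in blocks)
    if strand == "-":
        a, b = total - b, total - a
    out = []
    pos = 0
    for s, e in blocks:
        blen = e - s
        lo, hi = max(a, pos), min(b, pos + blen)
        if lo < hi:
            out.append((s + lo - pos, s + hi - pos))
        pos += blen
    return out


def _isoform_blocks(locus: SyntheticLocus) -> dict[str, list[tuple[int, int]]]:
    call = locus.splice_call()
    return splice_model.predict_isoforms(locus.gene, call)


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.asarray(list(seq))
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_cohort_reads(
    spec: CohortSpec,
    locus: SyntheticLocus,
    mode: str = "long",
    barcode_whitelist: Optional[list[str]] = None,
    with_sequences: bool = True,
) -> list[SimRead]:
    """Draw per-sample reads from allele-conditional isoform mixtures.

    Risk-haplotype transcripts are canonical / partial-retention /
    full-retention with the spec's probabilities; nonrisk transcripts follow
    their own (zero by default) rates. Long mode emits 3'-anchored reads with
    stochastic 5' truncation; short mode emits uniform fragments. Coordinates
    are drawn from a dedicated substream so ``with_sequences=False`` (skip
    base synthesis, used by coverage-only analyses) leaves them unchanged.
    """
    if mode not in ("long", "short"):
        raise ValueError(f"mode must be 'long' or 'short', got {mode}")
    if locus.gene.focal_intron_index is None:
        raise ValueError("retention requested but locus has no focal intron")
    if barcode_whitelist is None:
        barcode_whitelist = make_barcode_whitelist()

    coords_ss, bases_ss = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(coords_ss)
    seq_rng = np.random.default_rng(bases_ss)

    iso_blocks = _isoform_blocks(locus)
    gene = locus.gene
    vpos = gene.variant_site.pos
    chrom_seq = locus.chrom_seq

    # cache transcript sequences per (isoform, allele)
    tseq_cache: dict[tuple[str, str], str] = {}

    def transcript_seq(iso: str, allele: str) -> str:
        key = (iso, allele)
        if key not in tseq_cache:
            parts = []
            for s, e in iso_blocks[iso]:
                seg = chrom_seq[s:e]
                if s <= vpos < e and allele != chrom_seq[vpos]:
                    k = vpos - s
                    seg = seg[:k] + allele + seg[k + 1 :]
                parts.append(seg)
            genomic = "".join(parts)
            tseq_cache[key] = gene.transcript_orientation(genomic)
        return tseq_cache[key]

    iso_lens = {iso: sum(e - s for s, e in blocks) for iso, blocks in iso_blocks.items()}

    reads: list[SimRead] = []
    ridx = 0
    for gt in GENOTYPES:
        nsamp = spec.n_per_genotype.get(gt, 0)
        haps = {
            "GG": (RISK_ALLELE, RISK_ALLELE),
            "GT": (RISK_ALLELE, NONRISK_ALLELE),
            "TT": (NONRISK_ALLELE, NONRISK_ALLELE),
        }[gt]
        for si in range(nsamp):
            sample = f"{gt}_{si}"
            for _ in range(spec.depth_per_sample):
                allele = haps[rng.integers(0, 2)]
                pp, pf = spec.retention_rates.get(allele, (0.0, 0.0))
                u = rng.random()
                if u < pp:
                    iso = "partial_retention"
                elif u < pp + pf:
                    iso = "full_retention"
                else:
                    iso = "canonical"
                if iso != "canonical" and iso not in iso_blocks:
                    raise ValueError(
                        f"retention requested for allele {allele} but the locus variant "
                        "does not produce retention isoforms"
                    )
                L = iso_lens[iso]
                if mode == "long":
                    b = L  # 3' anchored (poly(A) end)
                    a = 0
                    if rng.random() < min(1.0, spec.truncation_per_kb * L / 1000):
                        a = int(rng.integers(0, max(1, L - spec.min_read_len)))
                else:
                    flen = int(np.clip(rng.normal(spec.read_length_mean, spec.read_length_sd),
                                       spec.min_read_len, L))
                    a = int(rng.integers(0, L - flen + 1))
                    b = a + flen
                blocks = _transcript_interval_to_blocks(iso_blocks[iso], gene.strand, a, b)
                barcode = barcode_whitelist[rng.integers(0, len(barcode_whitelist))]
                name = f"{sample}|{allele}|{iso}|{barcode}|r{ridx}"
                seq = None
                if with_sequences:
                    seq = transcript_seq(iso, allele)[a:b]
                    seq = _apply_errors(seq, seq_rng, spec.error_rate)
                reads.append(
                    SimRead(
                        name=name, sample=sample, genotype=gt, haplotype=allele,
                        isoform=iso, barcode=barcode, chrom=locus.chrom,
                        strand=gene.strand, blocks=blocks, seq=seq,
                    )
                )
                ridx += 1
    return reads


def truth_table(reads: list[SimRead], variant_pos: int) -> pd.DataFrame:
    rows = []
    for r in reads:
        covers = any(s <= variant_pos < e for s, e in r.blocks)
        rows.append(
            (r.name, r.sample, r.genotype, r.haplotype, r.isoform, r.barcode, int(covers))
        )
    return pd.DataFrame(
        rows,
        columns=["read_id", "sample", "genotype", "haplotype", "isoform", "barcode", "covers_variant"],
    )


def write_fastq(reads: list[SimRead], path: str, with_barcode: bool = True) -> None:
    """FASTQ of transcript-orientation cDNA, cell barcode prepended to the sequence."""
    with open(path, "w") as fh:
        for r in reads:
            if r.seq is None:
                raise ValueError("reads were simulated without sequences")
            seq = (r.barcode + r.seq) if with_barcode else r.seq
            fh.write(f"@{r.name}\n{seq}\n+\n{'?' * len(seq)}\n")


def write_truth_sam(reads: list[SimRead], locus: SyntheticLocus, path: str) -> None:
    """Error-free primary alignments (MAPQ 60) of the simulated cDNA reads."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": locus.chrom, "LN": len(locus.chrom_seq)}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            if r.seq is None:
                raise ValueError("reads were simulated without sequences")
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = r.blocks[0][0]
            a.mapping_quality = 60
            cigar = []
            prev_end = None
            for s, e in r.blocks:
                if prev_end is not None and s > prev_end:
                    cigar.append((3, s - prev_end))  # N
                cigar.append((0, e - s))  # M
                prev_end = e
            a.cigartuples = cigar
            sense = r.seq if r.strand == "+" else reverse_complement(r.seq)
            a.query_sequence = sense
            a.query_qualities = pysam.qualitystring_to_array("?" * len(sense))
            out.write(a)


# ---------------------------------------------------------------------------
# enzyme activity
# ---------------------------------------------------------------------------


@dataclass
class ActivityModel:
    """Generative linear model for enzyme activity: y = alpha + beta*g + N(0, sigma^2).

    ``g`` is risk-allele dosage (TT=0, GT=1, GG=2). The default noise sd is
    calibrated so the analytic OLS slope standard error at the default group
    sizes equals ``target_se`` (0.205 activity units), i.e.
    sigma = target_se * sqrt(Sxx).
    """

    intercept: float = 10.0  # µmol/L/h, typical normal-range activity
    slope: float = -0.449  # units per risk allele
    sigma: Optional[float] = None
    group_sizes: dict = field(default_factory=lambda: {"TT": 97, "GT": 99, "GG": 9})
    target_se: float = 0.205

    def __post_init__(self):
        if self.sigma is None:
            self.sigma = self.target_se * np.sqrt(self.sxx())
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 1")

    def dosages(self) -> np.ndarray:
        code = {"TT": 0, "GT": 1, "GG": 2}
        return np.concatenate(
            [np.full(self.group_sizes[gt], code[gt]) for gt in ("TT", "GT", "GG")]
        ).astype(float)

    def sxx(self) -> float:
        g = self.dosages()
        return float(((g - g.mean()) ** 2).sum())

    def analytic_slope_se(self) -> float:
        return float(self.sigma / np.sqrt(self.sxx()))


def simulate_gcase_cohort(am: ActivityModel, seed: int = 0) -> pd.DataFrame:
    """One activity value per individual under the linear dosage model."""
    rng = np.random.default_rng(seed)
    g = am.dosages()
    y = am.intercept + am.slope * g + rng.normal(0.0, am.sigma, size=len(g))
    gt = np.repeat(
        ["TT", "GT", "GG"], [am.group_sizes["TT"], am.group_sizes["GT"], am.group_sizes["GG"]]
    )
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(g))],
            "genotype": gt,
            "dosage": g.astype(int),
            "activity": y,
        }
    )


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


@dataclass
class MethylationModel:
    """Bernoulli per-read 5mC state at the variant-linked CpG, by allele."""

    p_meth: dict = field(default_factory=lambda: {RISK_ALLELE: 0.9, NONRISK_ALLELE: 0.1})
    calls_per_allele: dict = field(default_factory=lambda: {RISK_ALLELE: 500, NONRISK_ALLELE: 500})

    def __post_init__(self):
        for a, p in self.p_meth.items():
            if not (0 <= p <= 1):
                raise ValueError(f"p_meth[{a}]={p} outside [0, 1]")


def simulate_methylation_calls(mm: MethylationModel, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for allele in sorted(mm.calls_per_allele):
        n = mm.calls_per_allele[allele]
        if n == 0:
            continue
        calls = (rng.random(n) < mm.p_meth.get(allele, 0.0)).astype(int)
        for i, c in enumerate(calls):
            rows.append((f"{allele}_read{i}", allele, int(c)))
    return pd.DataFrame(rows, columns=["read_id", "allele", "methylated"])


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------


def write_vcf(locus: SyntheticLocus, path: str) -> None:
    v = locus.gene.variant_site
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={locus.chrom},length={len(locus.chrom_seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        fh.write(f"{locus.chrom}\t{v.pos + 1}\tvar1\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(
    outdir: str,
    cohort: Optional[CohortSpec] = None,
    activity: Optional[ActivityModel] = None,
    methylation: Optional[MethylationModel] = None,
    ref_seed: int = 0,
    seed: int = 0,
    short_window_len: Optional[int] = None,
    mode: str = "long",
) -> dict:
    """Write the complete fixture bundle and a checksum manifest.

    The reference (FASTA/GTF/BED/VCF) is generated from ``ref_seed`` and the
    stochastic outputs (reads, activity, methylation) from ``seed``, so
    changing ``seed`` leaves the reference files byte-identical.
    """
    os.makedirs(outdir, exist_ok=True)
    cohort = cohort or CohortSpec(seed=seed)
    activity = activity or ActivityModel()
    methylation = methylation or MethylationModel()

    locus = build_paralog_pair(seed=ref_seed)
    call = locus.splice_call()
    if short_window_len is None:
        short_window_len = call.retained_len or 40
    regions = build_region_set(locus.gene, short_window_len)

    paths = {
        "reference.fasta": lambda p: locus.write_fasta(p),
        "genes.gtf": lambda p: write_gtf([locus.gene, locus.gene.paralog], p),
        "regions.bed": lambda p: write_bed(regions, p),
        "variant.vcf": lambda p: write_vcf(locus, p),
    }
    for fname, writer in paths.items():
        writer(os.path.join(outdir, fname))

    cohort.seed = seed
    reads = simulate_cohort_reads(cohort, locus, mode=mode)
    write_fastq(reads, os.path.join(outdir, "reads.fastq"))
    write_truth_sam(reads, locus, os.path.join(outdir, "truth.sam"))
    truth_table(reads, locus.gene.variant_site.pos).to_csv(
        os.path.join(outdir, "truth.tsv"), sep="\t", index=False
    )
    simulate_gcase_cohort(activity, seed=seed).to_csv(
        os.path.join(outdir, "activity.tsv"), sep="\t", index=False
    )
    simulate_methylation_calls(methylation, seed=seed).to_csv(
        os.path.join(outdir, "methylation.tsv"), sep="\t", index=False
    )
    genotypes = pd.DataFrame(
        sorted({(r.sample, r.genotype) for r in reads}), columns=["sample", "genotype"]
    )
    genotypes.to_csv(os.path.join(outdir, "genotypes.tsv"), sep="\t", index=False)

    files = sorted(
        [
            "reference.fasta", "genes.gtf", "regions.bed", "variant.vcf",
            "reads.fastq", "truth.sam", "truth.tsv", "activity.tsv",
            "methylation.tsv", "genotypes.tsv",
        ]
    )
    manifest = {f: _sha256(os.path.join(outdir, f)) for f in files}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
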