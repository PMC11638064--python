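"""Allele-aware read analysis.

Covers allele-of-origin assignment at the variant site, haplotype purity of
retention-class reads, the allele-swap remapping control that rules out
variant-driven mismapping between the gene and its pseudogene, rule-based
isoform classification of long reads against the quantification regions,
cell-barcode demultiplexing with one allowed mismatch, and the per-allele
methylation contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .coverage_quant import AlignmentRecord, RETENTION_PROFILE, FilterProfile
from .gene_model import Region, RegionRole, VariantSite
from .stats import clopper_pearson, fisher_2x2

RISK = "risk"
NONRISK = "nonrisk"
OTHER = "other"
UNCOVERED = "uncovered"


@dataclass(frozen=True)
class AlleleCall:
    read_id: str
    allele: str  # risk | nonrisk | other | uncovered
    base: Optional[str]
    baseq: Optional[int] = None


def assign_allele(
    rec: AlignmentRecord,
    variant: VariantSite,
    risk_base: str,
    nonrisk_base: str,
    min_baseq: int = 0,
) -> AlleleCall:
    """Allele of origin from the read base mapped onto the variant site.

    Bases are compared on the sense strand (SAM SEQ orientation). Reads whose
    aligned span excludes the site are ``uncovered``; a covered base matching
    neither allele (sequencing error, N) is ``other``. When ``min_baseq`` > 0
    and the read carries qualities, a low-quality base is reported ``other``
    with its quality attached so callers can count exclusions.
    """
    base = rec.base_at(variant.pos)
    if base is None:
        return AlleleCall(rec.read_id, UNCOVERED, None)
    bq = rec.baseq_at(variant.pos)
    if min_baseq > 0 and bq is not None and bq < min_baseq:
        return AlleleCall(rec.read_id, OTHER, base, bq)
    if base == risk_base.upper():
        return AlleleCall(rec.read_id, RISK, base, bq)
    if base == nonrisk_base.upper():
        return AlleleCall(rec.read_id, NONRISK, base, bq)
    return AlleleCall(rec.read_id, OTHER, base, bq)


@dataclass(frozen=True)
class PurityResult:
    n_covered: int
    n_risk: int
    fraction_risk: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    defined: bool


def haplotype_purity(calls: Sequence[AlleleCall], alpha: float = 0.05) -> PurityResult:
    """Fraction of covered calls assigned to the risk allele, with an exact CI.

    Callers restrict ``calls`` to retention-class reads. Undefined (flagged)
    when no call covers the site.
    """
    covered = [c for c in calls if c.allele != UNCOVERED]
    if not covered:
        return PurityResult(0, 0, None, None, None, defined=False)
    k = sum(c.allele == RISK for c in covered)
    n = len(covered)
    lo, hi = clopper_pearson(k, n, alpha)
    return PurityResult(n, k, k / n, lo, hi, defined=True)


# ---------------------------------------------------------------------------
# allele-swap mapping control
# ---------------------------------------------------------------------------


def _aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap
    al.extend_gap_score = gap
    return al


@dataclass
class SwapControlResult:
    per_read: pd.DataFrame  # read_id, original_target, swapped_target, concordant, ambiguous
    concordance: Optional[float]
    n_evaluated: int
    n_ambiguous: int
    warning: Optional[str] = None


def allele_swap_control(
    records: Sequence[AlignmentRecord],
    variant: VariantSite,
    gene_seq: str,
    paralog_seq: Optional[str],
    risk_base: str,
    nonrisk_base: str,
) -> SwapControlResult:
    """Flip the variant base in each read and re-assign gene vs paralog.

    Each read covering the site is scored by full dynamic-programming
    alignment (match +1, mismatch -1, gap -2) against both the gene and the
    paralog reference sequence, before and after swapping risk/nonrisk at the
    variant position. A read is concordant when the winning reference is the
    same before and after the swap; reads with tied scores are flagged
    ambiguous and excluded from the rate. A sub-1 concordance warns that
    gene/paralog assignment is driven by the variant itself.
    """
    if paralog_seq is None:
        raise ValueError("allele-swap control requires a paralog reference")
    al = _aligner()
    swap = {risk_base.upper(): nonrisk_base.upper(), nonrisk_base.upper(): risk_base.upper()}
    rows = []
    n_conc = n_eval = n_amb = 0
    for rec in records:
        qi = rec._query_index(variant.pos)
        if qi is None or rec.seq is None:
            continue
        base = rec.seq[qi].upper()
        if base not in swap:
            continue
        flipped = rec.seq[:qi] + swap[base] + rec.seq[qi + 1 :]

        def best(seq: str) -> tuple[str, bool]:
            sg = al.score(gene_seq, seq)
            sp = al.score(paralog_seq, seq)
            if sg == sp:
                return "tie", True
            return ("gene" if sg > sp else "paralog"), False

        orig, amb0 = best(rec.seq)
        swpd, amb1 = best(flipped)
        ambiguous = amb0 or amb1
        concordant = (not ambiguous) and orig == swpd
        rows.append((rec.read_id, orig, swpd, concordant, ambiguous))
        if ambiguous:
            n_amb += 1
        else:
            n_eval += 1
            n_conc += concordant
    df = pd.DataFrame(
        rows, columns=["read_id", "original_target", "swapped_target", "concordant", "ambiguous"]
    )
    conc = n_conc / n_eval if n_eval else None
    warning = None
    if conc is not None and conc < 1.0:
        warning = "gene/paralog assignment changes with the variant base: mapping is variant-driven"
    return SwapControlResult(df, conc, n_eval, n_amb, warning)


# ---------------------------------------------------------------------------
# isoform classification
# ---------------------------------------------------------------------------

CANONICAL = "canonical"
PARTIAL = "partial_retention"
FULL = "full_retention"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class IsoformCall:
    read_id: str
    klass: str
    overlap_fractions: dict


def _covered_in(blocks: Sequence[tuple[int, int]], region: Region) -> int:
    return sum(
        max(0, min(e, region.end) - max(s, region.start)) for s, e in blocks
    )


def classify_isoform(
    rec: AlignmentRecord,
    regions: Sequence[Region],
    min_overlap: float = 0.8,
    min_intron_frac: float = 0.9,
    max_canonical_intron_bases: int = 2,
    profile: FilterProfile = RETENTION_PROFILE,
) -> IsoformCall:
    """Classify a long read as canonical / partial / full retention.

    full_retention: covers >= ``min_intron_frac`` of the full focal intron and
    touches the downstream exon. partial_retention: covers >= ``min_overlap``
    of the short intronic window plus downstream-exon bases while covering
    < ``min_intron_frac`` of the remaining intron. canonical: spans the
    exon-exon junction with at most ``max_canonical_intron_bases`` intronic
    bases. Anything else (including filter failures) is ambiguous.
    """
    by_role = {r.role: r for r in regions}
    intron = by_role[RegionRole.INTRON_FULL]
    window = by_role[RegionRole.INTRON_SHORT_WINDOW]
    rest = by_role[RegionRole.INTRON_REST]
    ex_up = by_role[RegionRole.EXON_UP]
    ex_down = by_role[RegionRole.EXON_DOWN]

    fr = {}
    if not profile.passes(rec) or rec.contig != intron.chrom:
        return IsoformCall(rec.read_id, AMBIGUOUS, fr)

    cov_intron = _covered_in(rec.blocks, intron)
    cov_window = _covered_in(rec.blocks, window)
    cov_rest = _covered_in(rec.blocks, rest)
    cov_up = _covered_in(rec.blocks, ex_up)
    cov_down = _covered_in(rec.blocks, ex_down)
    fr = {
        "intron_full": cov_intron / intron.length,
        "intron_short_window": cov_window / window.length,
        "intron_rest": cov_rest / rest.length if rest.length else 0.0,
        "exon_up": cov_up / ex_up.length,
        "exon_down": cov_down / ex_down.length,
    }

    if fr["intron_full"] >= min_intron_frac and cov_down > 0:
        return IsoformCall(rec.read_id, FULL, fr)
    if (
        fr["intron_short_window"] >= min_overlap
        and cov_down > 0
        and fr["intron_rest"] < min_intron_frac
    ):
        return IsoformCall(rec.read_id, PARTIAL, fr)
    if cov_up > 0 and cov_down > 0 and cov_intron <= max_canonical_intron_bases:
        return IsoformCall(rec.read_id, CANONICAL, fr)
    return IsoformCall(rec.read_id, AMBIGUOUS, fr)


# ---------------------------------------------------------------------------
# barcode demultiplexing
# ---------------------------------------------------------------------------


@dataclass
class DemuxResult:
    assignments: dict  # barcode -> list of read ids; key "unassigned" for the rest
    counts: pd.DataFrame  # barcode, n_reads
    observed_whitelist_ratio: float  # fraction of whitelist barcodes seen


def demux_barcodes(
    reads: Sequence[tuple[str, str]],
    whitelist: Sequence[str],
    max_mismatch: int = 1,
    barcode_len: Optional[int] = None,
) -> DemuxResult:
    """Assign each read to the unique whitelist barcode within ``max_mismatch``.

    ``reads`` are (read_id, sequence) pairs whose first ``barcode_len`` bases
    hold the cell barcode. Reads matching no barcode, or at least two at equal
    minimal distance, go to the ``unassigned`` bucket — never dropped.
    """
    wl = list(whitelist)
    if len(set(wl)) != len(wl):
        raise ValueError("whitelist contains duplicate barcodes")
    if not wl:
        raise ValueError("empty whitelist")
    blen = barcode_len or len(wl[0])
    if any(len(w) != blen for w in wl):
        raise ValueError("whitelist barcodes must share one length")
    assignments: dict[str, list[str]] = {w: [] for w in wl}
    assignments["unassigned"] = []
    for read_id, seq in reads:
        bc = seq[:blen].upper()
        dists = [(sum(a != b for a, b in zip(bc, w)), w) for w in wl]
        dists.sort()
        best_d, best_w = dists[0]
        unique = len(dists) == 1 or dists[1][0] > best_d
        if best_d <= max_mismatch and unique:
            assignments[best_w].append(read_id)
        else:
            assignments["unassigned"].append(read_id)
    counts = pd.DataFrame(
        [(w, len(ids)) for w, ids in assignments.items()], columns=["barcode", "n_reads"]
    )
    seen = sum(1 for w in wl if assignments[w])
    return DemuxResult(assignments, counts, seen / len(wl))


# ---------------------------------------------------------------------------
# methylation contrast
# ---------------------------------------------------------------------------


@dataclass
class MethylationContrast:
    fractions: dict  # allele -> methylated fraction
    counts: dict  # allele -> (methylated, unmethylated)
    odds_ratio: Optional[float]
    p: Optional[float]
    defined: bool  # False when only one allele observed


def methylation_by_allele(
    calls: pd.DataFrame, allele_a: str = "G", allele_b: str = "T"
) -> MethylationContrast:
    """Per-allele methylated fraction and two-sided Fisher exact contrast.

    ``calls`` needs columns ``allele`` and ``methylated`` (0/1). When one of
    the two alleles is absent the fractions of the present allele are still
    reported but the test is flagged undefined.
    """
    if not {"allele", "methylated"}.issubset(calls.columns):
        raise ValueError("calls need 'allele' and 'methylated' columns")
    counts = {}
    fractions = {}
    for allele in (allele_a, allele_b):
        sub = calls[calls["allele"] == allele]
        m = int(sub["methylated"].sum())
        u = int(len(sub) - m)
        if len(sub):
            counts[allele] = (m, u)
            fractions[allele] = m / len(sub)
    if len(counts) < 2:
        return MethylationContrast(fractions, counts, None, None, defined=False)
    table = [list(counts[allele_a]), list(counts[allele_b])]
    odds, p = fisher_2x2(table)
    return MethylationContrast(fractions, counts, odds, p, defined=p is not None)
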