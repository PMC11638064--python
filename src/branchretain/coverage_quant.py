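"""Regional depth with flag/quality filters, per-million normalization, dosage association.

Two distinct filter profiles exist because read retention and depth
calculation answer different questions: ``retention_profile`` (MAPQ >= 40,
primary only) decides which reads enter the analysis at all, while
``depth_profile`` (MAPQ >= 5, base quality >= 20, excluding unmapped /
secondary / QC-fail / duplicate records) mirrors the samtools-coverage-style
pileup filter used for the regional mean depth itself. Depth is counted by
reference span of the aligned blocks, so a deletion inside a block counts as
covered; ``count_deletions=False`` switches to aligned-base counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .gene_model import Region
from .stats import DosageRegressionResult, ols_dosage

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class FilterProfile:
    min_mapq: int = 5
    min_baseq: int = 20
    exclude_flags: int = FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_QCFAIL | FLAG_DUP

    def passes(self, rec: "AlignmentRecord") -> bool:
        return rec.mapq >= self.min_mapq and not (rec.flag & self.exclude_flags)


DEPTH_PROFILE = FilterProfile(min_mapq=5, min_baseq=20)
RETENTION_PROFILE = FilterProfile(
    min_mapq=40, min_baseq=0,
    exclude_flags=FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY | FLAG_QCFAIL | FLAG_DUP,
)


@dataclass
class AlignmentRecord:
    """Minimal alignment facts needed by depth and allele analyses."""

    read_id: str
    contig: str
    blocks: list  # aligned reference blocks, (start, end), sorted
    mapq: int
    flag: int = 0
    seq: Optional[str] = None  # sense-strand query sequence (SAM SEQ)
    quals: Optional[Sequence[int]] = None

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def is_primary(self) -> bool:
        return not (self.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY))

    @property
    def is_mapped(self) -> bool:
        return not (self.flag & FLAG_UNMAPPED)

    def _query_index(self, pos: int) -> Optional[int]:
        """Query-sequence index aligned to reference position ``pos`` (no indels)."""
        qoff = 0
        for s, e in self.blocks:
            if s <= pos < e:
                return qoff + (pos - s)
            qoff += e - s
        return None

    def base_at(self, pos: int) -> Optional[str]:
        qi = self._query_index(pos)
        if qi is None or self.seq is None:
            return None
        return self.seq[qi].upper()

    def baseq_at(self, pos: int) -> Optional[int]:
        qi = self._query_index(pos)
        if qi is None or self.quals is None:
            return None
        return int(self.quals[qi])

    @classmethod
    def from_pysam(cls, rec, merge_deletions: bool = True) -> "AlignmentRecord":
        """Build from a pysam record; N gaps always split blocks, D gaps
        split only when ``merge_deletions`` is False (the aligned-base dialect)."""
        quals = rec.query_qualities
        blocks: list[tuple[int, int]] = []
        pos = rec.reference_start
        for op, ln in rec.cigartuples or []:
            if op in (0, 7, 8):  # M, =, X
                if blocks and blocks[-1][1] == pos:
                    blocks[-1] = (blocks[-1][0], pos + ln)
                else:
                    blocks.append((pos, pos + ln))
                pos += ln
            elif op == 2:  # D
                if merge_deletions and blocks and blocks[-1][1] == pos:
                    blocks[-1] = (blocks[-1][0], pos + ln)
                pos += ln
            elif op == 3:  # N
                pos += ln
        return cls(
            read_id=rec.query_name,
            contig=rec.reference_name,
            blocks=blocks or [(rec.reference_start, rec.reference_start)],
            mapq=rec.mapping_quality,
            flag=rec.flag,
            seq=rec.query_sequence,
            quals=list(quals) if quals is not None else None,
        )

    @classmethod
    def from_sim_read(cls, read, mapq: int = 60) -> "AlignmentRecord":
        from .gene_model import reverse_complement

        seq = None
        if read.seq is not None:
            seq = read.seq if read.strand == "+" else reverse_complement(read.seq)
        return cls(
            read_id=read.name, contig=read.chrom, blocks=list(read.blocks),
            mapq=mapq, flag=16 if read.strand == "-" else 0, seq=seq,
            quals=[30] * sum(e - s for s, e in read.blocks) if seq is not None else None,
        )


def read_sam(path: str, contig: Optional[str] = None) -> list[AlignmentRecord]:
    import pysam

    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        return [
            AlignmentRecord.from_pysam(r)
            for r in fh
            if not r.is_unmapped and (contig is None or r.reference_name == contig)
        ]


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------


def mean_region_depth(
    alignments: Iterable[AlignmentRecord],
    region: Region,
    profile: FilterProfile = DEPTH_PROFILE,
) -> float:
    """Mean per-base pileup depth over ``region`` from filter-passing reads.

    Base-quality filtering applies only where the read carries quality values.
    Whether deletions inside a read count as covered is decided when the
    record's blocks are built (see ``AlignmentRecord.from_pysam``); spliced N
    gaps never count.
    """
    if region.length == 0:
        raise ValueError(f"empty region {region.name}")
    depth = np.zeros(region.length, dtype=np.int64)
    for rec in alignments:
        if rec.contig != region.chrom or not profile.passes(rec):
            continue
        for s, e in rec.blocks:
            lo, hi = max(s, region.start), min(e, region.end)
            if lo >= hi:
                continue
            if profile.min_baseq > 0 and rec.quals is not None:
                for pos in range(lo, hi):
                    bq = rec.baseq_at(pos)
                    if bq is None or bq >= profile.min_baseq:
                        depth[pos - region.start] += 1
            else:
                depth[lo - region.start : hi - region.start] += 1
    return float(depth.mean())


def count_mapped_reads(alignments: Iterable[AlignmentRecord]) -> int:
    """Denominator for per-million normalization: primary mapped reads only."""
    return sum(1 for r in alignments if r.is_mapped and r.is_primary)


def normalized_coverage(mean_depth: float, total_mapped_reads: int) -> float:
    """Mean depth divided by total mapped reads in millions."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return mean_depth / (total_mapped_reads / 1e6)


@dataclass(frozen=True)
class RegionCoverage:
    region: Region
    mean_depth: float
    total_mapped_reads: int

    @property
    def normalized(self) -> float:
        return normalized_coverage(self.mean_depth, self.total_mapped_reads)


def quantify_regions(
    alignments: Sequence[AlignmentRecord],
    regions: Sequence[Region],
    profile: FilterProfile = DEPTH_PROFILE,
    total_mapped_reads: Optional[int] = None,
) -> list[RegionCoverage]:
    if total_mapped_reads is None:
        total_mapped_reads = count_mapped_reads(alignments)
    return [
        RegionCoverage(region=r, mean_depth=mean_region_depth(alignments, r, profile),
                       total_mapped_reads=total_mapped_reads)
        for r in regions
    ]


def coverage_table(
    per_sample: dict, regions: Sequence[Region], genotypes: dict,
    profile: FilterProfile = DEPTH_PROFILE,
) -> pd.DataFrame:
    """Per-sample, per-region coverage table: sample, genotype, region, depth, normalized."""
    rows = []
    for sample, alignments in per_sample.items():
        total = count_mapped_reads(alignments)
        for r in regions:
            md = mean_region_depth(alignments, r, profile)
            rows.append((sample, genotypes[sample], r.name, md, normalized_coverage(md, total)))
    return pd.DataFrame(rows, columns=["sample", "genotype", "region", "mean_depth", "normalized"])


# ---------------------------------------------------------------------------
# genotype-dosage association
# ---------------------------------------------------------------------------

_DOSAGE = {"TT": 0, "GT": 1, "GG": 2}


def coverage_genotype_association(
    samples: Sequence[tuple[float, str]], gg_dosage_threshold: int = 5
) -> DosageRegressionResult:
    """Regress normalized coverage on genotype.

    With more than ``gg_dosage_threshold`` homozygous-risk (GG) samples the
    predictor is the three-level risk-allele dosage {0, 1, 2}; otherwise the
    sparse GG group is pooled with GT and the predictor is the binary
    risk-carrier indicator (GG+GT vs TT).
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    values = np.array([v for v, _ in samples], dtype=float)
    gts = [g for _, g in samples]
    bad = set(gts) - set(_DOSAGE)
    if bad:
        raise ValueError(f"unknown genotypes: {sorted(bad)}")
    if len(set(gts)) < 2:
        raise ValueError("no contrast: single genotype level")
    n_gg = sum(g == "GG" for g in gts)
    if n_gg > gg_dosage_threshold:
        g = np.array([_DOSAGE[x] for x in gts], dtype=float)
        grouping = "dosage"
    else:
        g = np.array([1.0 if x in ("GG", "GT") else 0.0 for x in gts])
        grouping = "binary"
    if np.var(g) == 0:
        raise ValueError("no contrast after grouping")
    return ols_dosage(values, g, grouping=grouping)
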