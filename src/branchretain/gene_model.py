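"""Gene/paralog coordinate model, HGVS-style intronic offsets and quantification regions.

All internal coordinates are 0-based half-open genomic intervals; HGVS and VCF
I/O are 1-based; BED output is 0-based half-open. Splice logic reasons in
transcript orientation: for a minus-strand gene the transcript sequence is the
reverse complement of the genomic sequence and "downstream" means lower
genomic coordinates.

The intronic offset convention follows HGVS ``c.<pos>-N``: offset ``N`` is the
1-based distance of an intronic base from the first base of the downstream
exon, counted in transcript orientation, so offset 1 is the intron base
adjacent to the acceptor exon (the terminal G of the acceptor AG dinucleotide).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RegionRole(str, Enum):
    EXON_UP = "exon_up"
    EXON_DOWN = "exon_down"
    INTRON_FULL = "intron_full"
    INTRON_SHORT_WINDOW = "intron_short_window"
    INTRON_REST = "intron_rest"
    GENE = "gene"
    PARALOG = "paralog"


@dataclass(frozen=True)
class Region:
    """A named genomic interval used for regional depth quantification."""

    name: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    role: RegionRole

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval for region {self.name}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IntronOffset:
    """HGVS-style intronic offset: distance upstream of the downstream exon, 1-based."""

    offset: int

    def __post_init__(self):
        if self.offset < 1:
            raise ValueError(f"intronic offset must be >= 1, got {self.offset}")


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV in genomic (sense-strand) coordinates and bases."""

    pos: int  # 0-based genomic position
    ref: str  # sense-strand reference base
    alt: str  # sense-strand alternate base


class HgvsParseError(ValueError):
    pass


_HGVS_RE = re.compile(
    r"^c\.(?P<exonpos>\d+)(?P<sign>[+-])(?P<offset>\d+)(?P<ref>[ACGT])>(?P<alt>[ACGT])$"
)


def parse_hgvs_offset(hgvs: str) -> tuple[IntronOffset, str, str]:
    """Parse an intronic acceptor-side HGVS SNV string such as ``c.1225-34C>A``.

    Returns the intronic offset and the ref/alt bases, both in transcript
    orientation (HGVS coding-sequence convention). Only acceptor-side
    (``-N``) offsets are supported; donor-side (``+N``) raises.
    """
    m = _HGVS_RE.match(hgvs.strip())
    if not m:
        raise HgvsParseError(f"cannot parse HGVS string {hgvs!r}: expected c.<pos>-<offset><ref>><alt>")
    if m.group("sign") == "+":
        raise HgvsParseError(
            f"donor-side offset {m.group('sign')}{m.group('offset')} unsupported in {hgvs!r}"
        )
    offset = int(m.group("offset"))
    if offset < 1:
        raise HgvsParseError(f"intronic offset must be >= 1, got {offset} in {hgvs!r}")
    return IntronOffset(offset), m.group("ref"), m.group("alt")


@dataclass
class GeneModel:
    """Exon/intron structure of a gene, optionally paired with a paralog.

    ``exons`` are genomic intervals sorted by start; ``focal_intron_index``
    indexes introns in *transcript* order (0 = first intron the spliceosome
    meets), so for a minus-strand gene it counts from the highest-coordinate
    intron downwards.
    """

    name: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    variant_site: Optional[VariantSite] = None
    focal_intron_index: Optional[int] = None
    paralog: Optional["GeneModel"] = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 > s1:
                raise ValueError("exons overlap or are unsorted")
        if any(e <= s for s, e in self.exons):
            raise ValueError("empty exon interval")

    # ---- derived structure -------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns_genomic(self) -> list[tuple[int, int]]:
        """Introns as genomic intervals in genomic (ascending) order."""
        return [(e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Introns as genomic intervals in transcript order."""
        gi = self.introns_genomic
        return gi if self.strand == "+" else gi[::-1]

    @property
    def exons_transcript_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def focal_intron(self) -> tuple[int, int]:
        if self.focal_intron_index is None:
            raise ValueError("no focal intron defined")
        return self.introns[self.focal_intron_index]

    def flanking_exons(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """(exon_up, exon_down) around the focal intron, transcript order."""
        i = self.focal_intron_index
        ex = self.exons_transcript_order
        return ex[i], ex[i + 1]

    # ---- coordinate conversion ---------------------------------------------

    def intron_offset_to_genomic(self, intron: tuple[int, int], off: IntronOffset) -> int:
        s, e = intron
        if off.offset > e - s:
            raise ValueError(f"offset {off.offset} exceeds intron length {e - s}")
        if self.strand == "+":
            return e - off.offset
        return s + off.offset - 1

    def genomic_to_intron_offset(self, intron: tuple[int, int], pos: int) -> IntronOffset:
        s, e = intron
        if not (s <= pos < e):
            raise ValueError(f"position {pos} not inside intron [{s}, {e})")
        if self.strand == "+":
            return IntronOffset(e - pos)
        return IntronOffset(pos - s + 1)

    def to_transcript_coords(self, pos: int) -> tuple[str, int]:
        """Locate a genomic position within the gene.

        Returns ``("intron", offset)`` with the HGVS-style intronic offset when
        the position is intronic, or ``("exon", i)`` with the 0-based
        transcript-order exon index when exonic.
        """
        lo, hi = self.span
        if not (lo <= pos < hi):
            raise ValueError(f"position {pos} outside gene span [{lo}, {hi})")
        for i, (s, e) in enumerate(self.exons_transcript_order):
            if s <= pos < e:
                return ("exon", i)
        for intron in self.introns:
            s, e = intron
            if s <= pos < e:
                return ("intron", self.genomic_to_intron_offset(intron, pos).offset)
        raise AssertionError("unreachable: position inside span but in no exon/intron")

    # ---- sequence access ---------------------------------------------------

    def transcript_orientation(self, seq: str) -> str:
        return seq if self.strand == "+" else reverse_complement(seq)

    def intron_seq(self, reference: str, intron: tuple[int, int]) -> str:
        """Intron sequence in transcript orientation (starts GT, ends AG)."""
        s, e = intron
        return self.transcript_orientation(reference[s:e])

    def validate_splice_sites(self, reference: str) -> None:
        """Check every intron starts with the GT donor and ends with the AG acceptor."""
        for intron in self.introns:
            seq = self.intron_seq(reference, intron).upper()
            if not seq.startswith("GT"):
                raise ValueError(f"intron {intron} lacks GT donor (saw {seq[:2]})")
            if not seq.endswith("AG"):
                raise ValueError(f"intron {intron} lacks AG acceptor (saw {seq[-2:]})")
        if self.variant_site is not None and self.focal_intron_index is not None:
            s, e = self.focal_intron()
            if not (s <= self.variant_site.pos < e):
                raise ValueError("variant site is not inside the focal intron")


def build_region_set(model: GeneModel, short_window_len: int) -> list[Region]:
    """Build the named quantification regions around the focal intron.

    Emits exon_up, exon_down, intron_full, intron_short_window (the
    ``short_window_len`` intronic bases adjacent to the downstream exon in
    transcript orientation), intron_rest, gene and (if present) paralog.
    The short window and the rest partition the full intron exactly.
    """
    if short_window_len <= 0:
        raise ValueError(f"short_window_len must be positive, got {short_window_len}")
    s, e = model.focal_intron()
    if short_window_len > e - s:
        raise ValueError(f"short_window_len {short_window_len} exceeds focal intron length {e - s}")
    exon_up, exon_down = model.flanking_exons()
    if model.strand == "+":
        win = (e - short_window_len, e)
        rest = (s, e - short_window_len)
    else:
        win = (s, s + short_window_len)
        rest = (s + short_window_len, e)
    c = model.chrom
    regions = [
        Region("exon_up", c, exon_up[0], exon_up[1], RegionRole.EXON_UP),
        Region("exon_down", c, exon_down[0], exon_down[1], RegionRole.EXON_DOWN),
        Region("intron_full", c, s, e, RegionRole.INTRON_FULL),
        Region("intron_short_window", c, win[0], win[1], RegionRole.INTRON_SHORT_WINDOW),
        Region("intron_rest", c, rest[0], rest[1], RegionRole.INTRON_REST),
        Region("gene", c, model.span[0], model.span[1], RegionRole.GENE),
    ]
    if model.paralog is not None:
        p = model.paralog
        regions.append(Region("paralog", p.chrom, p.span[0], p.span[1], RegionRole.PARALOG))
    return regions


# ---- BED / GTF I/O ---------------------------------------------------------


def write_bed(regions: list[Region], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t+\n")


def read_bed(path: str) -> list[Region]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            try:
                role = RegionRole(name)
            except ValueError:
                role = RegionRole.GENE
            regions.append(Region(name, chrom, start, end, role))
    return regions


def write_gtf(models: list[GeneModel], path: str, source: str = "branchretain") -> None:
    """Write gene models as GTF (1-based inclusive coordinates, gene_id attribute)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.name}"; transcript_id "{m.name}.t1";'
            lo, hi = m.span
            fh.write(f"{m.chrom}\t{source}\ttranscript\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t{attrs}\n")
            for s, e in m.exons:
                fh.write(f"{m.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")


def read_gtf(path: str) -> list[GeneModel]:
    """Read gene models back from GTF written by :func:`write_gtf`."""
    by_gene: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            m = re.search(r'gene_id "([^"]+)"', f[8])
            gid = m.group(1) if m else "unknown"
            rec = by_gene.setdefault(gid, {"chrom": f[0], "strand": f[6], "exons": []})
            rec["exons"].append((int(f[3]) - 1, int(f[4])))
    return [
        GeneModel(name=gid, chrom=rec["chrom"], strand=rec["strand"], exons=rec["exons"])
        for gid, rec in by_gene.items()
    ]
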