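"""Rule-based branchpoint and cryptic 3' splice-site analysis.

The model: the spliceosome selects a branchpoint adenosine, normally 18-44 nt
upstream of the 3' splice site, inside a degenerate pyrimidine-rich motif.
A variant that replaces that A disables lariat formation at the normal branch
site; splicing either fails (full intron retention) or re-routes through an
alternative AG acceptor upstream of the branchpoint, leaving the 3'-terminal
segment of the intron in the mature transcript (partial retention).

All offsets here are HGVS-style intronic offsets in transcript orientation:
offset 1 is the intronic base adjacent to the downstream exon (the acceptor G).
Scoring is a fixed hand-weighted consensus around the candidate A — a
pyrimidine at -2 (weight 0.25), U at -1 (weight 0.5), a pyrimidine at +1
(weight 0.25), normalized to [0, 1]. This deliberately captures only the A's
identity and local pyrimidine context, not a trained branchpoint model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .gene_model import GeneModel, IntronOffset

PYRIMIDINES = frozenset("CTU")

DEFAULT_BP_WINDOW = (18, 44)


@dataclass(frozen=True)
class BranchpointCandidate:
    """A candidate branchpoint adenosine inside the search window."""

    offset: int  # intronic offset of the A, transcript orientation
    motif_score: float
    window_rank: int  # 1-based rank after sorting


@dataclass
class SpliceCall:
    """Complete branchpoint-disruption call for one intron/variant pair."""

    primary_bp: Optional[BranchpointCandidate]
    disrupted: bool
    alt_bp: Optional[BranchpointCandidate] = None
    cryptic_acceptor: Optional[int] = None  # offset of the 3'-most base (G) of the cryptic AG
    retained_len: Optional[int] = None
    bp_to_acceptor_gap: Optional[int] = None  # cryptic G offset - branchpoint offset
    predicted_isoforms: frozenset = frozenset({"canonical"})
    candidates: list = field(default_factory=list)


def _offset_base(intron_seq: str, offset: int) -> str:
    """Base at a given intronic offset; offset 1 = last base of the intron."""
    return intron_seq[len(intron_seq) - offset].upper()


def score_branchpoint_context(intron_seq: str, offset: int) -> float:
    """Consensus score of the A at ``offset``: 0.25*y(-2) + 0.5*U(-1) + 0.25*y(+1)."""
    L = len(intron_seq)
    score = 0.0
    # -1/-2 are 5' of the A (larger offsets); +1 is 3' (smaller offset)
    if offset + 2 <= L and _offset_base(intron_seq, offset + 2) in PYRIMIDINES:
        score += 0.25
    if offset + 1 <= L and _offset_base(intron_seq, offset + 1) in "TU":
        score += 0.5
    if offset - 1 >= 1 and _offset_base(intron_seq, offset - 1) in PYRIMIDINES:
        score += 0.25
    return score


def enumerate_branchpoints(
    intron_seq: str, window: tuple[int, int] = DEFAULT_BP_WINDOW
) -> list[BranchpointCandidate]:
    """Rank every adenosine whose offset lies in ``window`` (inclusive).

    Sorted by motif score (descending), ties broken by proximity to the 3'
    splice site (smaller offset wins). Empty list when the window holds no A.
    """
    seq = intron_seq.upper()
    if not seq.endswith("AG"):
        raise ValueError("intron sequence must end with the AG acceptor")
    lo, hi = window
    if lo < 1 or hi > len(seq):
        raise ValueError(f"window {window} outside intron of length {len(seq)}")
    hits = []
    for off in range(lo, hi + 1):
        if _offset_base(seq, off) == "A":
            hits.append((off, score_branchpoint_context(seq, off)))
    hits.sort(key=lambda t: (-t[1], t[0]))
    return [
        BranchpointCandidate(offset=off, motif_score=sc, window_rank=i + 1)
        for i, (off, sc) in enumerate(hits)
    ]


def assess_variant_effect(
    candidates: list[BranchpointCandidate],
    variant_offset: int,
    ref_base: str,
    alt_base: str,
) -> tuple[bool, Optional[BranchpointCandidate]]:
    """Decide whether the variant destroys the top-ranked branchpoint.

    ``ref_base``/``alt_base`` are in transcript orientation. Disrupted iff the
    variant sits exactly on the top candidate's A and converts it to a non-A
    base; the alternative branchpoint is then the best remaining candidate.
    """
    if not candidates:
        return False, None
    top = candidates[0]
    disrupted = (
        variant_offset == top.offset
        and ref_base.upper() == "A"
        and alt_base.upper() != "A"
    )
    alt_bp = None
    if disrupted:
        remaining = [c for c in candidates if c.offset != variant_offset]
        alt_bp = remaining[0] if remaining else None
    return disrupted, alt_bp


def scan_cryptic_acceptor(
    intron_seq: str, disrupted_bp_offset: int
) -> tuple[Optional[int], Optional[int]]:
    """Find the nearest AG 5' of the disrupted branchpoint.

    Scans toward the intron 5' end (increasing offsets) for the first AG
    dinucleotide whose G lies strictly 5' of the branchpoint. Returns
    ``(cryptic_acceptor_offset, retained_len)`` where the acceptor offset is
    that of the G (the 3'-most base of the AG) and the retained segment is
    every intronic base 3' of the AG through the intron end — so
    ``retained_len = acceptor_offset - 1``. ``(None, None)`` when no AG exists.
    """
    seq = intron_seq.upper()
    L = len(seq)
    for g_off in range(disrupted_bp_offset + 1, L):
        if _offset_base(seq, g_off) == "G" and _offset_base(seq, g_off + 1) == "A":
            return g_off, g_off - 1
    return None, None


def call_splice_disruption(
    intron_seq: str,
    variant_offset: int,
    ref_base: str,
    alt_base: str,
    window: tuple[int, int] = DEFAULT_BP_WINDOW,
) -> SpliceCall:
    """Run the full branchpoint pipeline: enumerate, assess, scan, predict."""
    candidates = enumerate_branchpoints(intron_seq, window)
    disrupted, alt_bp = assess_variant_effect(candidates, variant_offset, ref_base, alt_base)
    call = SpliceCall(
        primary_bp=candidates[0] if candidates else None,
        disrupted=disrupted,
        alt_bp=alt_bp,
        candidates=candidates,
    )
    if disrupted:
        acc, retained = scan_cryptic_acceptor(intron_seq, variant_offset)
        call.cryptic_acceptor = acc
        call.retained_len = retained
        if acc is not None:
            call.bp_to_acceptor_gap = acc - variant_offset
            call.predicted_isoforms = frozenset({"canonical", "partial_retention", "full_retention"})
        else:
            call.predicted_isoforms = frozenset({"canonical", "full_retention"})
    else:
        call.predicted_isoforms = frozenset({"canonical"})
    return call


# ---- isoform interval prediction -------------------------------------------


def predict_isoforms(model: GeneModel, call: SpliceCall) -> dict[str, list[tuple[int, int]]]:
    """Genomic exon-block models for each predicted isoform.

    canonical: the annotated exons. full_retention: exons with the focal
    intron unspliced (flanking exons fused through the intron).
    partial_retention: canonical plus the retained intronic segment fused to
    the downstream exon. Blocks are merged, sorted genomic intervals.
    """
    exons = list(model.exons)
    out = {"canonical": exons}
    if not call.disrupted:
        return out
    s, e = model.focal_intron()
    if "full_retention" in call.predicted_isoforms:
        out["full_retention"] = _merge_blocks(exons + [(s, e)])
    if call.retained_len is not None and "partial_retention" in call.predicted_isoforms:
        if model.strand == "+":
            retained = (e - call.retained_len, e)
        else:
            retained = (s, s + call.retained_len)
        out["partial_retention"] = _merge_blocks(exons + [retained])
    return out


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    blocks = sorted(blocks)
    merged = [list(blocks[0])]
    for s, e in blocks[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(b) for b in merged]


def write_isoform_gtf(
    model: GeneModel, isoforms: dict[str, list[tuple[int, int]]], path: str
) -> None:
    with open(path, "w") as fh:
        for iso, blocks in isoforms.items():
            attrs = f'gene_id "{model.name}"; transcript_id "{model.name}.{iso}";'
            fh.write(
                f"{model.chrom}\tbranchretain\ttranscript\t{blocks[0][0] + 1}\t{blocks[-1][1]}\t.\t{model.strand}\t.\t{attrs}\n"
            )
            for s, e in blocks:
                fh.write(
                    f"{model.chrom}\tbranchretain\texon\t{s + 1}\t{e}\t.\t{model.strand}\t.\t{attrs}\n"
                )
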